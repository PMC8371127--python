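"""End-to-end orchestration with a reproducibility manifest.

A run is described by a flat key=value config (stages, paths, seed,
model settings).  Stages execute in dependency order; every run writes
``manifest.json`` capturing the resolved config, the seed, SHA-256
checksums of all inputs, and the package version, so two runs with
equal manifests produce bitwise-equal TSV/Newick outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

from . import __version__
from .formats import (
    read_alignment,
    read_hypotheses,
    read_trait_matrix,
    read_tree,
    write_alignment,
    write_trait_matrix,
    write_tree,
)

__all__ = ["PipelineError", "load_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "rates", "slowfast", "autest", "dollo", "profiles")

_DEFAULTS = {
    "stages": "simulate,rates,slowfast",
    "out_dir": "pipeline_out",
    "seed": "1",
    "n_taxa": "12",
    "n_sites": "1000",
    "alpha": "0.5",
    "K": "4",
    "step": "0.05",
    "bootstrap": "100",
    "loss_prob": "0.1",
    "n_traits": "200",
    "metric": "pearson_complement",
    "pcoa_axes": "2",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = 1):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Flat key=value file; CLI overrides take precedence."""
    config = dict(_DEFAULTS)
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise PipelineError(
                    "config", f"line {lineno}: expected key=value, got {line!r}", 2
                )
            key, value = line.split("=", 1)
            config[key.strip()] = value.strip()
    if overrides:
        config.update({k: str(v) for k, v in overrides.items() if v is not None})
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require_input(config: dict, key: str, stage: str) -> Path:
    value = config.get(key)
    if not value:
        raise PipelineError(stage, f"config key {key!r} is required", 2)
    p = Path(value)
    if not p.exists():
        raise PipelineError(stage, f"input file not found: {p}", 2)
    return p


def run_pipeline(config: dict, log=None) -> dict:
    """Execute the selected stages; returns the manifest dict."""
    import numpy as np

    def say(msg: str) -> None:
        if log is not None:
            print(msg, file=log)

    stages = [s.strip() for s in config["stages"].split(",") if s.strip()]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError("config", f"unknown stage(s): {sorted(unknown)}", 2)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    inputs: dict[str, str] = {}

    tree = alignment = profile = None

    if "simulate" in stages:
        from .simulate import SimConfig, simulate_alignment, simulate_traits, simulate_tree

        say("simulate: generating tree, alignment and traits")
        sim = SimConfig(
            n_taxa=int(config["n_taxa"]),
            seed=seed,
            alpha=float(config["alpha"]),
            n_sites=int(config["n_sites"]),
            loss_prob=float(config["loss_prob"]),
            n_traits=int(config["n_traits"]),
        )
        tree = simulate_tree(sim)
        alignment, true_rates = simulate_alignment(tree, sim)
        traits, _ = simulate_traits(tree, sim)
        write_tree(tree, out_dir / "sim_tree.nwk")
        write_alignment(alignment, out_dir / "sim_alignment.fasta")
        write_trait_matrix(traits, out_dir / "sim_traits.tsv")
        with open(out_dir / "sim_true_rates.tsv", "w", newline="\n") as fh:
            fh.write("site\ttrue_rate\n")
            for i, r in enumerate(true_rates, 1):
                fh.write(f"{i}\t{r:.10g}\n")
    else:
        if {"rates", "slowfast", "autest"} & set(stages):
            tree_path = _require_input(config, "tree", "input")
            aln_path = _require_input(config, "alignment", "input")
            inputs["tree"] = _sha256(tree_path)
            inputs["alignment"] = _sha256(aln_path)
            tree = read_tree(tree_path)
            dialect = "phylip-relaxed" if str(aln_path).endswith((".phy", ".phylip")) else "fasta"
            alignment = read_alignment(aln_path, dialect)

    if "rates" in stages:
        from .site_rates import posterior_mean_rates

        say("rates: fitting alpha and posterior-mean site rates")
        profile = posterior_mean_rates(tree, alignment, K=int(config["K"]))
        table = profile.to_table()
        with open(out_dir / "site_rates.tsv", "w", newline="\n") as fh:
            table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        say(f"rates: alpha_hat = {profile.alpha_hat:.4f}")

    if "slowfast" in stages:
        from .slowfast import support_curve

        say("slowfast: building support curves")
        if "hypotheses" in config and config["hypotheses"]:
            hyp_path = _require_input(config, "hypotheses", "slowfast")
            inputs["hypotheses"] = _sha256(hyp_path)
            hypotheses = read_hypotheses(hyp_path)
        else:
            # default: trace the first non-trivial split of the input tree
            from .formats import Hypothesis, tree_splits

            splits = sorted(tree_splits(tree), key=lambda s: (len(s), sorted(s)))
            if not splits:
                raise PipelineError("slowfast", "tree has no non-trivial splits")
            hypotheses = [Hypothesis("split1", splits[0])]
        curve = support_curve(
            alignment,
            tree,
            hypotheses,
            step=float(config["step"]),
            n_bootstrap=int(config["bootstrap"]),
            seed=seed,
            K=int(config["K"]),
            alpha=profile.alpha_hat if profile is not None else None,
        )
        with open(out_dir / "curve.tsv", "w", newline="\n") as fh:
            curve.to_table().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    if "autest" in stages:
        from .topotests import au_test, constrained_site_logliks

        say("autest: constrained topologies, RELL and AU p-values")
        trees_path = _require_input(config, "test_trees", "autest")
        inputs["test_trees"] = _sha256(trees_path)
        import dendropy

        tree_list = dendropy.TreeList.get(
            path=str(trees_path), schema="newick", preserve_underscores=True
        )
        matrix = constrained_site_logliks(
            alignment,
            list(tree_list),
            alpha=float(config["alpha"]),
            K=int(config["K"]),
        )
        result = au_test(matrix, seed=seed, n_rep=int(config.get("au_reps", "10000")))
        with open(out_dir / "au.tsv", "w", newline="\n") as fh:
            result.to_table().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    if "dollo" in stages or "profiles" in stages:
        traits_path = config.get("traits")
        if traits_path:
            traits_path = _require_input(config, "traits", "dollo")
            inputs["traits"] = _sha256(traits_path)
            cat_path = config.get("categories") or None
            if cat_path:
                inputs["categories"] = _sha256(_require_input(config, "categories", "dollo"))
            traits = read_trait_matrix(traits_path, cat_path)
        elif "simulate" in stages:
            traits = read_trait_matrix(out_dir / "sim_traits.tsv")
        else:
            raise PipelineError("dollo", "config key 'traits' is required", 2)

    if "dollo" in stages:
        from .dollo import dollo_reconstruct, gain_loss_table, node_percentages

        say("dollo: ancestral presence and gain/loss dynamics")
        if tree is None:
            tree_path = _require_input(config, "tree", "dollo")
            inputs["tree"] = _sha256(tree_path)
            tree = read_tree(tree_path, rooted=True)
        tree.is_rooted = True
        state_map = dollo_reconstruct(tree, traits)
        with open(out_dir / "dollo_states.tsv", "w", newline="\n") as fh:
            node_percentages(state_map).to_csv(fh, sep="\t", float_format="%.1f")
        with open(out_dir / "dollo_events.tsv", "w", newline="\n") as fh:
            gain_loss_table(state_map).to_csv(fh, sep="\t")

    if "profiles" in stages:
        from .profiles import heatmap_order, pcoa, profile_distance, ward_cluster

        say("profiles: distances, PCoA and Ward clustering")
        dist = profile_distance(traits, metric=config["metric"])
        with open(out_dir / "profile_distances.tsv", "w", newline="\n") as fh:
            dist.to_frame().to_csv(fh, sep="\t", float_format="%.10g")
        ordination = pcoa(dist, n_axes=int(config["pcoa_axes"]))
        with open(out_dir / "pcoa_coordinates.tsv", "w", newline="\n") as fh:
            ordination.to_frame().to_csv(fh, sep="\t", float_format="%.10g")
        rows = ward_cluster(traits, "species_pearson")
        cols = ward_cluster(traits, "orthologs_euclidean")
        with open(out_dir / "species_dendrogram.nwk", "w", newline="\n") as fh:
            fh.write(rows.to_newick() + "\n")
        with open(out_dir / "ordered_matrix.tsv", "w", newline="\n") as fh:
            heatmap_order(traits, rows, cols).to_csv(fh, sep="\t")

    manifest = {
        "package_version": __version__,
        "config": {k: config[k] for k in sorted(config)},
        "seed": seed,
        "input_checksums": inputs,
        "stages_run": stages,
    }
    with open(out_dir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    say("done")
    return manifest
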