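"""End-to-end study replay: simulate -> alpha -> beta -> diff -> network ->
markers -> mia, with a machine-readable manifest.

Every stage writes its outputs under one run directory and records their
SHA-256 hashes; re-running with the same configuration reproduces identical
hashes.  Stages never mutate another stage's inputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import alphadiv, betadiv, difftax, markers, network, synthdata
from .io_tables import (
    DistanceMatrix,
    OtuTable,
    ValidationError,
    metadata_frame,
    read_metadata,
    read_newick,
    read_otu_table,
    write_distance_matrix,
    write_edge_list,
    write_graphml,
    write_metadata,
    write_newick,
    write_otu_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Parameters for a full pipeline run (flat, one field per knob)."""

    out_dir: str = "run"
    seed: int = 0
    # inputs; all three empty -> simulate them
    table_path: str = ""
    metadata_path: str = ""
    tree_path: str = ""
    # simulate
    n_otus: int = 405
    n_diff_per_habitat: int = 20
    log2_fold_change: float = 2.0
    asd_enriched_fraction: float = 0.35
    cooc_block_size: int = 6
    # alpha
    rarefaction_depth: int = 0  # 0 -> min sample total
    # beta
    beta_metric: str = "w-unifrac"
    n_permutations: int = 999
    # diff
    diff_rank: str = "otu"
    # network
    rho_threshold: float = 0.5
    # markers / mia
    n_top: int = 60
    folds: int = 10
    cv_trials: int = 2
    cv_trees: int = 100
    mia_scale: str = "counts"
    mia_mode: str = "grid"

    def validate(self) -> None:
        if self.folds < 2 or self.cv_trials < 1 or self.n_top < 1:
            raise ValidationError("folds >= 2, cv_trials >= 1, n_top >= 1 required")
        if not 0 <= self.rho_threshold <= 1:
            raise ValidationError("rho_threshold must lie in [0, 1]")
        if self.beta_metric not in ("uw-unifrac", "w-unifrac"):
            raise ValidationError(f"unknown beta metric {self.beta_metric!r}")
        if self.mia_scale not in ("counts", "relative"):
            raise ValidationError(f"unknown MIA scale {self.mia_scale!r}")
        if self.diff_rank not in betadiv.RANKS:
            raise ValidationError(f"unknown rank {self.diff_rank!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat ``key = value`` config file (sections optional);
        keyword overrides win."""
        parser = configparser.ConfigParser()
        text = Path(path).read_text()
        if not text.lstrip().startswith("["):
            text = "[run]\n" + text
        parser.read_string(text)
        values: dict[str, str] = {}
        for section in parser.sections():
            values.update(parser.items(section))
        kwargs = {}
        for f in fields(cls):
            if f.name in values:
                raw = values[f.name]
                kwargs[f.name] = type(f.default)(raw) if f.default != "" else raw
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


class _Manifest:
    def __init__(self, config: RunConfig):
        self.stages: list[dict] = []
        self.config = {f.name: getattr(config, f.name) for f in fields(RunConfig)}

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "parameters": params,
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            }
        )
        logger.info("stage %s: %d output file(s)", stage, len(outputs))

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps({"config": self.config, "stages": self.stages}, indent=2)
            + "\n"
        )


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)

    # -- stage 1: simulate (or load) -------------------------------------
    if config.table_path:
        try:
            table = read_otu_table(config.table_path)
            records = read_metadata(config.metadata_path)
            tree = read_newick(config.tree_path)
        except Exception as exc:
            raise ValidationError(f"stage simulate/load failed: {exc}") from exc
        truth = []
        manifest.record("simulate", {"loaded": True}, [])
    else:
        synth_config = synthdata.SynthConfig(
            n_otus=config.n_otus,
            n_diff_per_habitat=config.n_diff_per_habitat,
            log2_fold_change=config.log2_fold_change,
            asd_enriched_fraction=config.asd_enriched_fraction,
            cooc_block_size=config.cooc_block_size,
            seed=config.seed,
        )
        table, records, tree, truth = synthdata.generate_study(synth_config)
        write_otu_table(table, out / "table.tsv")
        write_metadata(records, out / "metadata.tsv")
        write_newick(tree, out / "tree.nwk")
        with (out / "truth.tsv").open("w") as fh:
            fh.write("otu_id\thabitat\tdirection\tlog2_fold_change\n")
            for t in truth:
                fh.write(f"{t.otu_id}\t{t.habitat}\t{t.direction}\t{t.log2_fold_change!r}\n")
        manifest.record(
            "simulate",
            {"n_otus": config.n_otus, "seed": config.seed},
            [out / "table.tsv", out / "metadata.tsv", out / "tree.nwk", out / "truth.tsv"],
        )

    meta = metadata_frame(records)
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(
            f"stage simulate: samples missing from metadata: {missing}"
        )

    # -- stage 2: alpha ---------------------------------------------------
    depth = config.rarefaction_depth or None
    alpha = alphadiv.alpha_summary(table, depth=depth, seed=config.seed)
    groups = alphadiv.compare_groups(alpha, meta)
    _write_tsv(alpha, out / "alpha.tsv")
    _write_tsv(groups, out / "alpha_groups.tsv", index=False)
    manifest.record(
        "alpha",
        {"depth": int(alpha["rarefaction_depth"].iloc[0])},
        [out / "alpha.tsv", out / "alpha_groups.tsv"],
    )

    # -- stage 3: beta ----------------------------------------------------
    dm = betadiv.distance_matrix(table, tree, config.beta_metric)
    write_distance_matrix(dm, out / "distance.tsv")
    ordination = betadiv.pcoa(dm)
    coords = pd.DataFrame(
        ordination.coordinates[:, : min(4, ordination.coordinates.shape[1])],
        index=ordination.sample_ids,
    )
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    _write_tsv(coords, out / "pcoa.tsv")
    contrasts = []
    sample_meta = meta.loc[table.sample_ids]
    rng = np.random.default_rng(config.seed)
    # habitat contrast over all samples, then disease within each habitat
    tests = [("habitat", np.ones(len(table.sample_ids), bool), "habitat")]
    for hab in sorted(sample_meta["habitat"].unique()):
        tests.append((f"group|{hab}", (sample_meta["habitat"] == hab).to_numpy(), "group"))
    for name, mask, column in tests:
        ids = [s for s, m in zip(table.sample_ids, mask) if m]
        sub = DistanceMatrix(ids, dm.data[np.ix_(mask, mask)])
        res = betadiv.permanova(
            sub,
            sample_meta.loc[ids, column],
            n_permutations=config.n_permutations,
            seed=int(rng.integers(0, 2**31)),
        )
        contrasts.append(
            {
                "contrast": name,
                "pseudo_F": res.pseudo_F,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
    _write_tsv(pd.DataFrame(contrasts), out / "permanova.tsv", index=False)
    manifest.record(
        "beta",
        {"metric": config.beta_metric, "permutations": config.n_permutations},
        [out / "distance.tsv", out / "pcoa.tsv", out / "permanova.tsv"],
    )

    # -- stage 4: diff ----------------------------------------------------
    diff = difftax.differential_screen(table, meta, rank=config.diff_rank)
    diff_df = difftax.diff_frame(diff)
    _write_tsv(diff_df, out / "diff.tsv", index=False)
    clincorr = difftax.clinical_correlation(table, meta)
    _write_tsv(clincorr.to_long(), out / "clinical_correlation.tsv", index=False)
    manifest.record(
        "diff",
        {"rank": config.diff_rank},
        [out / "diff.tsv", out / "clinical_correlation.tsv"],
    )

    # -- stage 5: network -------------------------------------------------
    net_outputs = []
    stats_rows = []
    for hab in sorted(sample_meta["habitat"].unique()):
        significant = diff_df[
            (diff_df["habitat"] == hab) & diff_df["significant"]
        ]
        directions = dict(zip(significant["taxon_id"], significant["direction"]))
        for grp in sorted(sample_meta["group"].unique()):
            ids = [
                s
                for s in table.sample_ids
                if sample_meta.loc[s, "habitat"] == hab
                and sample_meta.loc[s, "group"] == grp
            ]
            tag = f"{grp}_{hab}"
            if len(significant) < 2 or len(ids) < 4:
                logger.warning("network %s skipped: too few markers or samples", tag)
                stats_rows.append({"network": tag, "n_nodes": 0, "n_edges": 0,
                                   "n_components": 0, "skipped": True})
                continue
            net = network.build_network(
                table.select_samples(ids),
                list(significant["taxon_id"]),
                threshold=config.rho_threshold,
                directions=directions,
            )
            write_graphml(net.graph, out / f"network_{tag}.graphml")
            write_edge_list(net.graph, out / f"network_{tag}.edges.tsv")
            net_outputs += [out / f"network_{tag}.graphml", out / f"network_{tag}.edges.tsv"]
            stats = network.network_stats(net)
            stats_rows.append(
                {
                    "network": tag,
                    "n_nodes": stats["n_nodes"],
                    "n_edges": stats["n_edges"],
                    "n_components": stats["n_components"],
                    "skipped": False,
                }
            )
    _write_tsv(pd.DataFrame(stats_rows), out / "network_stats.tsv", index=False)
    manifest.record(
        "network",
        {"threshold": config.rho_threshold},
        net_outputs + [out / "network_stats.tsv"],
    )

    # -- stage 6: markers -------------------------------------------------
    marker_outputs = []
    rankings: dict[str, markers.MarkerRanking] = {}
    habitat_tables: dict[str, OtuTable] = {}
    habitat_labels: dict[str, np.ndarray] = {}
    ks = _cv_grid(config.n_top)
    for hab in sorted(sample_meta["habitat"].unique()):
        ids = [s for s in table.sample_ids if sample_meta.loc[s, "habitat"] == hab]
        sub = table.select_samples(ids)
        labels = sample_meta.loc[ids, "group"].to_numpy()
        directions = dict(
            zip(
                diff_df[diff_df["habitat"] == hab]["taxon_id"],
                diff_df[diff_df["habitat"] == hab]["direction"],
            )
        ) if config.diff_rank == "otu" else None
        ranking = markers.rf_rank(
            sub, labels, n_top=config.n_top, seed=config.seed,
            directions=directions, n_estimators=config.cv_trees,
        )
        curve = markers.cv_error_curve(
            sub, labels, ranking, folds=config.folds, trials=config.cv_trials,
            seed=config.seed, n_estimators=config.cv_trees, k_grid=ks,
        )
        rankings[hab] = ranking
        habitat_tables[hab] = sub
        habitat_labels[hab] = labels
        _write_tsv(ranking.to_frame(), out / f"ranking_{hab}.tsv", index=False)
        _write_tsv(
            pd.DataFrame({"k": curve.ks, "error": curve.errors}),
            out / f"cv_curve_{hab}.tsv",
            index=False,
        )
        marker_outputs += [out / f"ranking_{hab}.tsv", out / f"cv_curve_{hab}.tsv"]
    manifest.record(
        "markers",
        {"n_top": config.n_top, "folds": config.folds, "trials": config.cv_trials},
        marker_outputs,
    )

    # -- stage 7: mia -----------------------------------------------------
    mia_outputs = []
    for hab, ranking in rankings.items():
        panels = markers.enumerate_panels(
            ranking, habitat_tables[hab], habitat_labels[hab],
            mode=config.mia_mode, scale=config.mia_scale,
        )
        rows = [
            {
                "panel": p.name,
                "m": len(p.asd_otus),
                "n": len(p.control_otus),
                "auc": p.auc,
                "cutoff": p.cutoff,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
            }
            for p in panels
        ]
        _write_tsv(pd.DataFrame(rows), out / f"mia_panels_{hab}.tsv", index=False)
        best = markers.best_panel(panels)
        predictions = markers.classify(best.scores.to_numpy(), best.cutoff)
        _write_tsv(
            pd.DataFrame(
                {
                    "sample_id": best.scores.index,
                    "mia": best.scores.to_numpy(),
                    "predicted": predictions,
                }
            ),
            out / f"mia_predictions_{hab}.tsv",
            index=False,
        )
        mia_outputs += [out / f"mia_panels_{hab}.tsv", out / f"mia_predictions_{hab}.tsv"]
    manifest.record(
        "mia", {"scale": config.mia_scale, "mode": config.mia_mode}, mia_outputs
    )

    manifest.write(out / "manifest.json")
    return json.loads((out / "manifest.json").read_text())


def _cv_grid(n_top: int) -> list[int]:
    """Dense for small k, strided above 10, always including n_top."""
    ks = list(range(1, min(10, n_top) + 1))
    ks += list(range(12, n_top + 1, 4))
    if ks[-1] != n_top:
        ks.append(n_top)
    return ks
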