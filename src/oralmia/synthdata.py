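"""Synthetic two-group, two-habitat OTU study generator.

Produces count tables, sample metadata, a random phylogeny and a ground-truth
record of spiked (differentially abundant) OTUs, with the statistical
structure the downstream analyses assume:

* habitat-specific base compositions (log-normal means, normalized), so the
  saliva/plaque contrast dominates the disease contrast;
* Dirichlet-multinomial counts around the group x habitat composition
  (one concentration knob controls overdispersion);
* per-habitat spiked OTUs whose base means are multiplied or divided by
  ``2**log2_fold_change`` in the disease group;
* an optional latent-factor co-variation block among control-enriched OTUs in
  control samples (drives co-occurrence network contrasts);
* clinical covariates, with the behavioural severity score built to correlate
  positively with each subject's summed relative abundance of
  disease-enriched markers.

Identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .io_tables import GROUPS, HABITATS, OtuTable, PhyloTree, SampleRecord, ValidationError

__all__ = ["SynthConfig", "SpikedOtu", "generate_study", "generate_tree"]

_GROUP_ORDER = (
    ("control", "saliva"),
    ("control", "plaque"),
    ("ASD", "saliva"),
    ("ASD", "plaque"),
)
_PREFIX = {
    ("control", "saliva"): "HS",
    ("control", "plaque"): "HP",
    ("ASD", "saliva"): "AS",
    ("ASD", "plaque"): "AP",
}

# Small pool of plausible oral lineages used to label synthetic OTUs.
_LINEAGES = [
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Haemophilus"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Alloprevotella"),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Leptotrichiaceae", "Leptotrichia"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Actinomycetaceae", "Actinomyces"),
    ("Actinobacteria", "Actinobacteria", "Micrococcales", "Micrococcaceae", "Rothia"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Porphyromonas"),
    ("Firmicutes", "Negativicutes", "Selenomonadales", "Selenomonadaceae", "Selenomonas"),
    ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "Neisseria"),
    ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Treponemataceae", "Treponema"),
]


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults reproduce the emulated study shape
    (405 OTUs, 27/26/32/26 samples, depth 33959 +/- 4253)."""

    n_otus: int = 405
    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("control", "saliva"): 27,
            ("control", "plaque"): 26,
            ("ASD", "saliva"): 32,
            ("ASD", "plaque"): 26,
        }
    )
    depth_mean: float = 33959.0
    depth_sd: float = 4253.0
    n_diff_per_habitat: int = 20
    log2_fold_change: float = 2.0
    #: Fraction of spiked OTUs enriched in the disease group (rest are
    #: control-enriched, i.e. depleted under disease).
    asd_enriched_fraction: float = 0.35
    base_abundance_sigma: float = 1.5
    dirichlet_concentration: float = 300.0
    clinical_corr: float = 0.4
    #: Size of the latent-factor co-variation block planted among
    #: control-enriched spiked OTUs (0 disables it).
    cooc_block_size: int = 0
    cooc_block_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_otus < 2:
            raise ValidationError("n_otus must be >= 2")
        if not self.group_sizes:
            raise ValidationError("group_sizes must be non-empty")
        for (group, habitat), n in self.group_sizes.items():
            if group not in GROUPS or habitat not in HABITATS:
                raise ValidationError(f"unknown group/habitat {(group, habitat)!r}")
            if n <= 0:
                raise ValidationError("all group sizes must be > 0")
        if self.depth_mean <= 0 or self.depth_sd < 0:
            raise ValidationError("depth_mean must be > 0 and depth_sd >= 0")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be > 0")
        if not 0 <= self.n_diff_per_habitat <= self.n_otus:
            raise ValidationError("n_diff_per_habitat must lie in [0, n_otus]")
        if not 0.0 <= self.asd_enriched_fraction <= 1.0:
            raise ValidationError("asd_enriched_fraction must lie in [0, 1]")
        if not math.isfinite(self.log2_fold_change):
            raise ValidationError("log2_fold_change must be finite")
        try:
            fold = 2.0 ** abs(self.log2_fold_change)
        except OverflowError:
            fold = math.inf
        if not math.isfinite(fold) or fold <= 0:
            raise ValidationError(
                "log2_fold_change would drive spiked base means to zero or overflow"
            )
        if not -1.0 < self.clinical_corr < 1.0:
            raise ValidationError("clinical_corr must lie in (-1, 1)")
        if self.cooc_block_size < 0:
            raise ValidationError("cooc_block_size must be >= 0")
        n_ctrl = self.n_diff_per_habitat - round(
            self.asd_enriched_fraction * self.n_diff_per_habitat
        )
        if self.cooc_block_size > n_ctrl:
            raise ValidationError(
                "cooc_block_size exceeds the number of control-enriched spiked OTUs"
            )


@dataclass(frozen=True)
class SpikedOtu:
    """Ground-truth record of one planted differential OTU."""

    otu_id: str
    habitat: str
    direction: str  # "ASD-enriched" | "control-enriched"
    log2_fold_change: float


def _make_taxonomy(
    otu_ids: Sequence[str], rng: np.random.Generator
) -> dict[str, str]:
    choices = rng.integers(0, len(_LINEAGES), size=len(otu_ids))
    taxonomy = {}
    for otu, k in zip(otu_ids, choices):
        phylum, cls, order, fam, genus = _LINEAGES[k]
        # one pseudo-genus per handful of OTUs so genus aggregation is non-trivial
        sub = int(otu.lstrip("OTU")) % 7
        genus_name = f"{genus}_{sub}" if sub else genus
        taxonomy[otu] = ";".join(
            [phylum, cls, order, fam, genus_name, f"{genus_name} sp{otu.lstrip('OTU')}"]
        )
    return taxonomy


def generate_study(
    config: SynthConfig,
) -> tuple[OtuTable, list[SampleRecord], PhyloTree, list[SpikedOtu]]:
    """Draw one complete synthetic study.

    Returns the count table, per-sample metadata, a random phylogeny over the
    OTU ids and the list of spiked OTUs with their planted directions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_otus
    otu_ids = [f"OTU{i + 1:03d}" for i in range(n)]
    taxonomy = _make_taxonomy(otu_ids, rng)

    habitats = sorted({h for _, h in config.group_sizes})
    base: dict[str, np.ndarray] = {}
    for habitat in habitats:
        raw = rng.lognormal(mean=0.0, sigma=config.base_abundance_sigma, size=n)
        base[habitat] = raw / raw.sum()

    fold = 2.0 ** config.log2_fold_change
    n_asd = round(config.asd_enriched_fraction * config.n_diff_per_habitat)
    truth: list[SpikedOtu] = []
    comp: dict[tuple[str, str], np.ndarray] = {}
    block_idx: dict[str, np.ndarray] = {}
    for habitat in habitats:
        spiked = rng.choice(n, size=config.n_diff_per_habitat, replace=False)
        asd_idx, ctrl_idx = spiked[:n_asd], spiked[n_asd:]
        asd_mean = base[habitat].copy()
        asd_mean[asd_idx] *= fold
        asd_mean[ctrl_idx] /= fold
        if not np.all(asd_mean > 0) or not np.all(np.isfinite(asd_mean)):
            raise ValidationError(
                "fold change drove a spiked base mean to zero or overflow"
            )
        comp[("control", habitat)] = base[habitat]
        comp[("ASD", habitat)] = asd_mean / asd_mean.sum()
        # block the most abundant control-enriched spikes so the shared
        # latent factor dominates multinomial noise
        by_abundance = ctrl_idx[np.argsort(-base[habitat][ctrl_idx], kind="stable")]
        block_idx[habitat] = by_abundance[: config.cooc_block_size]
        for i in asd_idx:
            truth.append(
                SpikedOtu(otu_ids[i], habitat, "ASD-enriched", config.log2_fold_change)
            )
        for i in ctrl_idx:
            truth.append(
                SpikedOtu(otu_ids[i], habitat, "control-enriched", config.log2_fold_change)
            )
        # give each spiked OTU a unique genus so genus-level screens see it
        for i in np.concatenate([asd_idx, ctrl_idx]):
            lineage = taxonomy[otu_ids[i]].split(";")
            lineage[4] = f"{lineage[4].split('_')[0]}_sp{otu_ids[i].lstrip('OTU')}"
            lineage[5] = f"{lineage[4]} sp"
            taxonomy[otu_ids[i]] = ";".join(lineage)

    sample_ids: list[str] = []
    subject_of: list[str] = []
    labels: list[tuple[str, str]] = []
    counts_cols: list[np.ndarray] = []
    asd_sets = {
        h: np.array(
            [int(t.otu_id.lstrip("OTU")) - 1 for t in truth
             if t.habitat == h and t.direction == "ASD-enriched"],
            dtype=int,
        )
        for h in habitats
    }
    marker_load: dict[str, list[float]] = {}

    for group, habitat in _GROUP_ORDER:
        count = config.group_sizes.get((group, habitat), 0)
        prefix = _PREFIX[(group, habitat)]
        subj_prefix = "A" if group == "ASD" else "C"
        for k in range(count):
            sid = f"{prefix}{k + 1:02d}"
            subject = f"{subj_prefix}{k + 1:02d}"
            depth = int(max(1000, round(rng.normal(config.depth_mean, config.depth_sd))))
            mean = comp[(group, habitat)].copy()
            if group == "control" and len(block_idx[habitat]):
                factor = math.exp(config.cooc_block_sigma * rng.normal())
                mean[block_idx[habitat]] *= factor
                mean /= mean.sum()
            p = rng.dirichlet(config.dirichlet_concentration * mean)
            col = rng.multinomial(depth, p)
            sample_ids.append(sid)
            subject_of.append(subject)
            labels.append((group, habitat))
            counts_cols.append(col)
            if group == "ASD":
                rel = col / col.sum()
                marker_load.setdefault(subject, []).append(
                    float(rel[asd_sets[habitat]].sum()) if len(asd_sets[habitat]) else 0.0
                )

    counts = np.column_stack(counts_cols)
    table = OtuTable(otu_ids, sample_ids, counts, taxonomy)

    records = _make_metadata(
        rng, sample_ids, subject_of, labels, marker_load, config.clinical_corr
    )
    tree = generate_tree(otu_ids, seed=int(rng.integers(0, 2**31)))
    return table, records, tree, truth


# Table-shaped clinical priors (mean, sd) for (ASD, control).
_CLINICAL_PRIORS = {
    "age": ((10.02, 1.43), (10.19, 0.59)),
    "bmi": ((19.59, 3.60), (19.92, 4.53)),
    "dmft": ((2.03, 1.79), (1.04, 1.86)),
    "dmfs": ((3.91, 3.83), (1.96, 3.86)),
    "pli": ((1.88, 0.43), (1.88, 0.34)),
    "gi": ((0.90, 0.44), (0.25, 0.47)),
    "bi": ((1.02, 0.72), (0.25, 0.47)),
    "bop": ((0.69, 0.56), (0.31, 0.45)),
    "pd": ((1.92, 0.37), (1.81, 0.47)),
}
_ABC_MEAN, _ABC_SD = 78.66, 26.46


def _make_metadata(
    rng: np.random.Generator,
    sample_ids: list[str],
    subject_of: list[str],
    labels: list[tuple[str, str]],
    marker_load: dict[str, list[float]],
    clinical_corr: float,
) -> list[SampleRecord]:
    # subject-level draws so a subject's two samples share covariates
    subjects = sorted(set(subject_of))
    subj_group = {s: g for s, (g, _) in zip(subject_of, labels)}
    values: dict[str, dict[str, float]] = {s: {} for s in subjects}
    for s in subjects:
        col = 0 if subj_group[s] == "ASD" else 1
        for name, priors in _CLINICAL_PRIORS.items():
            mu, sd = priors[col]
            values[s][name] = float(max(0.0, rng.normal(mu, sd)))
        values[s]["sex"] = "F" if rng.random() < 0.18 else "M"

    asd_subjects = [s for s in subjects if subj_group[s] == "ASD"]
    if asd_subjects:
        load = np.array([float(np.mean(marker_load.get(s, [0.0]))) for s in asd_subjects])
        sd = load.std()
        z = (load - load.mean()) / sd if sd > 0 else np.zeros_like(load)
        noise = rng.normal(size=len(asd_subjects))
        latent = clinical_corr * z + math.sqrt(1 - clinical_corr**2) * noise
        abc = np.maximum(0.0, _ABC_MEAN + _ABC_SD * latent)
        for s, a in zip(asd_subjects, abc):
            values[s]["abc_score"] = float(a)

    records = []
    for sid, subj, (group, habitat) in zip(sample_ids, subject_of, labels):
        v = values[subj]
        records.append(
            SampleRecord(
                sample_id=sid,
                subject_id=subj,
                group=group,
                habitat=habitat,
                age=v["age"],
                sex=v["sex"],
                bmi=v["bmi"],
                abc_score=v.get("abc_score"),
                dmft=v["dmft"],
                dmfs=v["dmfs"],
                pli=v["pli"],
                gi=v["gi"],
                bi=v["bi"],
                bop=v["bop"],
                pd=v["pd"],
            )
        )
    return records


def generate_tree(otu_ids: Sequence[str], seed: int) -> PhyloTree:
    """Random bifurcating rooted tree over ``otu_ids``.

    Topology by sequential random joins; branch lengths i.i.d. exponential(1).
    """
    ids = list(otu_ids)
    if len(ids) < 2:
        raise ValidationError("need at least 2 OTU ids")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate OTU ids")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=o) for o in ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        a, b = nodes[i], nodes[j]
        a.length = float(rng.exponential(1.0))
        b.length = float(rng.exponential(1.0))
        parent = TreeNode(children=[a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    nodes[0].length = 0.0
    return PhyloTree(nodes[0])
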