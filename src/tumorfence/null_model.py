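"""Permutation null for fencing enrichment, p-values, FDR and the FPM.

The null keeps every cell position and every tumor cell fixed and reassigns
the multiset of non-tumor phenotype labels to the non-tumor positions by a
uniformly random permutation.  Geometry (and hence the contact graph) never
changes; only which positions carry the queried phenotype g does.  The
p-value for a slide is the fraction of permuted configurations whose
fencing-cell count f_r is at least the observed f_d, and the fencing
participation metric is

    FPM = max(0, (f_d - <f_r>) / f_d)        (0 when f_d = 0)

so FPM = 1 means the permuted slides never place g-cells in fencing
clusters, and 0 means the observed fencing is no more than random.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .data import CellRecord, Slide, filter_eligible
from .fencing import FencingConfig, build_neighbor_graph, find_fencing

__all__ = [
    "PermutationEnsemble",
    "FpmRecord",
    "OccurrenceSummary",
    "permute_noncancer_labels",
    "fencing_pvalue",
    "bh_significant",
    "compute_fpm",
    "occurrence_frequency",
    "sensitivity_scan",
    "analyze_cohort",
]


@dataclass
class PermutationEnsemble:
    """Null ensemble of fencing-cell counts f_r for one (slide, phenotype)."""

    n_perm: int
    seed: int
    f_r_values: np.ndarray

    @property
    def mean_f_r(self) -> float:
        return float(np.mean(self.f_r_values))


@dataclass
class FpmRecord:
    """Per-(slide, phenotype) fencing summary against the permutation null."""

    slide_id: str
    patient_id: str
    phenotype: str
    f_d: int
    mean_f_r: float
    p_value: float
    fpm: float
    significant: bool | None = None  # filled in after BH across the family


@dataclass
class OccurrenceSummary:
    """Cohort-level occurrence frequency f_p of significant fencing."""

    phenotype: str
    n_eligible_slides: int
    n_significant: int

    @property
    def f_p(self) -> float:
        return self.n_significant / self.n_eligible_slides


def _substream(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-(slide, phenotype) RNG substream from a master seed."""
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(t.encode()) for t in tokens
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def permute_noncancer_labels(slide: Slide, seed: int | np.random.Generator) -> Slide:
    """Return a slide with non-tumor labels uniformly permuted over
    non-tumor positions; tumor cells and all positions are untouched."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    non_idx = [i for i, c in enumerate(slide.cells) if not c.is_tumor]
    if len(non_idx) < 2:
        raise ValueError("need at least 2 non-tumor cells to permute")
    labels = [slide.cells[i].phenotype for i in non_idx]
    order = rng.permutation(len(non_idx))
    new_cells = list(slide.cells)
    for k, i in enumerate(non_idx):
        c = slide.cells[i]
        new_cells[i] = CellRecord(
            cell_id=c.cell_id,
            x=c.x,
            y=c.y,
            phenotype=labels[order[k]],
            is_tumor=False,
        )
    return Slide(
        slide_id=slide.slide_id,
        patient_id=slide.patient_id,
        cells=new_cells,
        extent=slide.extent,
    )


class _NullEngine:
    """Precomputed fixed-geometry structures for fast permutation sampling.

    Because a uniform label permutation makes the set of g-positions a
    uniformly random size-n_g subset of the non-tumor positions, each null
    draw reduces to sampling such a subset and recounting fencing cells on
    the fixed contact graph.
    """

    def __init__(self, slide: Slide, r_c: float):
        self.graph = build_neighbor_graph(slide.cells, r_c)
        tumor = slide.tumor_mask()
        touch_all = (
            np.asarray(self.graph.adjacency.dot(tumor.astype(np.int64))).ravel() > 0
        )
        self.non_idx = np.flatnonzero(~tumor)
        self.m = len(self.non_idx)
        # contact edges with both endpoints non-tumor, reindexed 0..m-1
        remap = -np.ones(self.graph.n, dtype=np.intp)
        remap[self.non_idx] = np.arange(self.m)
        e = self.graph.edges
        if len(e):
            both = (~tumor[e[:, 0]]) & (~tumor[e[:, 1]])
            self.edges = remap[e[both]]
        else:
            self.edges = np.empty((0, 2), dtype=np.intp)
        self.touch = touch_all[self.non_idx]

    def count_f(self, member: np.ndarray, N_F: int) -> int:
        """f_d for a boolean g-membership mask over non-tumor cells."""
        if not member.any():
            return 0
        e = self.edges
        if len(e):
            keep = member[e[:, 0]] & member[e[:, 1]]
            e = e[keep]
        m = self.m
        adj = sparse.csr_matrix(
            (np.ones(len(e), dtype=np.int8), (e[:, 0], e[:, 1])), shape=(m, m)
        )
        n_comp, labels = connected_components(adj, directed=False)
        sel = np.flatnonzero(member)
        sizes = np.bincount(labels[sel], minlength=n_comp)
        touch_any = np.zeros(n_comp, dtype=bool)
        np.logical_or.at(touch_any, labels[sel], self.touch[sel])
        good = (sizes >= N_F) & touch_any
        return int(sizes[good].sum())

    def sample_f_r(
        self, n_g: int, n_perm: int, N_F: int, rng: np.random.Generator
    ) -> np.ndarray:
        out = np.empty(n_perm, dtype=np.int64)
        member = np.zeros(self.m, dtype=bool)
        for k in range(n_perm):
            member[:] = False
            member[rng.permutation(self.m)[:n_g]] = True
            out[k] = self.count_f(member, N_F)
        return out


def fencing_pvalue(
    slide: Slide,
    phenotype: str,
    config: FencingConfig = FencingConfig(),
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[int, PermutationEnsemble, float]:
    """Observed f_d, null ensemble, and permutation p-value for one slide.

    p = #{permutations with f_r >= f_d} / n_perm (plain fraction; with
    n_perm >= 1000 the smallest resolvable p is 0, reported as < 1/n_perm
    in text output).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    engine = _NullEngine(slide, config.r_c)
    g_mask_all = np.array(
        [c.phenotype == phenotype and not c.is_tumor for c in slide.cells]
    )
    member = g_mask_all[engine.non_idx]
    f_d = engine.count_f(member, config.N_F)
    rng = _substream(seed, slide.slide_id, phenotype)
    f_r = engine.sample_f_r(int(member.sum()), n_perm, config.N_F, rng)
    p = float(np.mean(f_r >= f_d))
    return f_d, PermutationEnsemble(n_perm=n_perm, seed=seed, f_r_values=f_r), p


def bh_significant(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over one family of p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def compute_fpm(f_d: float, mean_f_r: float) -> float:
    """FPM = max(0, (f_d - <f_r>)/f_d); defined as 0 when f_d = 0."""
    if f_d < 0 or mean_f_r < 0:
        raise ValueError("counts must be non-negative")
    if f_d == 0:
        return 0.0
    return max(0.0, (f_d - mean_f_r) / f_d)


def occurrence_frequency(records: list[FpmRecord]) -> OccurrenceSummary:
    """Fraction f_p of eligible slides significant after BH, one phenotype."""
    if not records:
        raise ValueError("no eligible slides: occurrence frequency undefined")
    phenos = {r.phenotype for r in records}
    if len(phenos) != 1:
        raise ValueError("records must come from a single phenotype family")
    if any(r.significant is None for r in records):
        raise ValueError("records must be BH-adjudicated first")
    return OccurrenceSummary(
        phenotype=records[0].phenotype,
        n_eligible_slides=len(records),
        n_significant=sum(bool(r.significant) for r in records),
    )


def analyze_cohort(
    slides: list[Slide],
    phenotype: str,
    config: FencingConfig = FencingConfig(),
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
    min_g: int = 50,
    min_tumor: int = 50,
) -> tuple[list[FpmRecord], OccurrenceSummary | None]:
    """Per-slide FPM records with BH significance across the cohort family.

    Ineligible slides are skipped (recorded by omission, not fatal).  One BH
    family spans all eligible slides of the cohort for this phenotype.
    """
    records: list[FpmRecord] = []
    for slide in slides:
        if not filter_eligible(slide, phenotype, min_g=min_g, min_tumor=min_tumor):
            continue
        f_d, ens, p = fencing_pvalue(slide, phenotype, config, n_perm, seed)
        records.append(
            FpmRecord(
                slide_id=slide.slide_id,
                patient_id=slide.patient_id,
                phenotype=phenotype,
                f_d=f_d,
                mean_f_r=ens.mean_f_r,
                p_value=p,
                fpm=compute_fpm(f_d, ens.mean_f_r),
            )
        )
    if not records:
        return records, None
    mask = bh_significant([r.p_value for r in records], q=q)
    for r, sig in zip(records, mask):
        r.significant = bool(sig)
    return records, occurrence_frequency(records)


def sensitivity_scan(
    slide: Slide,
    phenotype: str,
    config: FencingConfig = FencingConfig(),
    n_perm: int = 1000,
    seed: int = 0,
    delta_r: float = 5.0,
    delta_n: int = 1,
) -> pd.DataFrame:
    """FPM under independent perturbations of r_c (±delta_r) and N_F (±delta_n).

    Returns a tidy frame with one row per (r_c, N_F) setting, including the
    base configuration.  The permutation seed schedule is fixed, so the scan
    is reproducible.
    """
    settings = [(config.r_c, config.N_F)]
    for dr in (-delta_r, delta_r):
        settings.append((config.r_c + dr, config.N_F))
    for dn in (-delta_n, delta_n):
        if config.N_F + dn >= 1:
            settings.append((config.r_c, config.N_F + dn))
    rows = []
    for r_c, n_f in settings:
        cfg = FencingConfig(r_c=r_c, N_F=n_f)
        f_d, ens, p = fencing_pvalue(slide, phenotype, cfg, n_perm, seed)
        rows.append(
            {
                "r_c": r_c,
                "N_F": n_f,
                "f_d": f_d,
                "mean_f_r": ens.mean_f_r,
                "p_value": p,
                "fpm": compute_fpm(f_d, ens.mean_f_r),
            }
        )
    return pd.DataFrame(rows)


def records_to_frame(records: list[FpmRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "slide_id": r.slide_id,
                "patient_id": r.patient_id,
                "phenotype": r.phenotype,
                "f_d": r.f_d,
                "mean_f_r": r.mean_f_r,
                "p_value": r.p_value,
                "fpm": r.fpm,
                "significant": r.significant,
            }
            for r in records
        ]
    )
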