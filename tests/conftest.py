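"""Shared fixtures: hand-built micro-slides and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from tumorfence.data import CellRecord, Slide


def make_slide(points, slide_id="s1", patient_id="p1", extent=(1000.0, 1000.0)):
    """Build a slide from (x, y, phenotype) triples; 'Tumor' marks tumor."""
    cells = [
        CellRecord(f"c{i:04d}", float(x), float(y), ph, ph == "Tumor")
        for i, (x, y, ph) in enumerate(points)
    ]
    return Slide(slide_id, patient_id, cells, extent=extent)


def random_slide(rng, n=120, labels=("g", "other", "Tumor"), extent=(400.0, 400.0)):
    """Uniformly scattered multi-phenotype slide for oracle comparisons."""
    pts = [
        (rng.uniform(0, extent[0]), rng.uniform(0, extent[1]), labels[rng.integers(len(labels))])
        for _ in range(n)
    ]
    return make_slide(pts, extent=extent)


def brute_force_fencing(slide, phenotype, r_c=30.0, N_F=3):
    """All-pairs O(n²) reference for clusters and f_d (union-find)."""
    pos = slide.positions()
    n = len(pos)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    adj = d2 <= r_c**2
    np.fill_diagonal(adj, False)
    ph = slide.phenotypes()
    tumor = slide.tumor_mask()

    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    gsel = np.flatnonzero(ph == phenotype)
    for i in gsel:
        for j in gsel:
            if i < j and adj[i, j]:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in gsel:
        comps.setdefault(find(i), set()).add(int(i))
    clusters = [frozenset(c) for c in comps.values() if len(c) >= N_F]
    fencing = [
        c for c in clusters if any(adj[i, j] for i in c for j in np.flatnonzero(tumor))
    ]
    f_d = sum(len(c) for c in fencing)
    return sorted(clusters, key=min), sorted(fencing, key=min), f_d


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
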