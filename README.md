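# tumorfence

Detection and mechanistic modeling of **fencing** — the physical encirclement
of tumor cells by clusters of a single non-tumor phenotype — in spatial
single-cell data such as imaging mass cytometry (IMC) of ~1 mm² tumor
microarray cores.

The package is aimed at computational biologists analyzing per-cell centroid
tables (position, phenotype label, tumor flag) together with patient
outcomes, and at modelers asking what a fence *does*: whether a wall of
cells on the tumor rim shields the tumor from cytotoxic lymphocytes or,
by secreting chemokines, recruits them.

## What it computes

**Fencing clusters.** Cells are nodes of a contact graph with an edge
whenever two centroids lie within r_c = 30 μm. A cluster of phenotype *g*
is a connected component of the *g*-induced subgraph with at least
N_F = 3 members; it is a *fencing* cluster if any member touches a tumor
cell. f_d counts the *g*-cells in fencing clusters.

**Fencing participation metric (FPM).** Against a permutation null that
freezes every position and tumor cell and reshuffles the non-tumor labels,

    FPM = max(0, (f_d − ⟨f_r⟩) / f_d),

where ⟨f_r⟩ is the mean fencing-cell count over ≥ 1000 permuted slides.
Per-slide p-values (the fraction of permutations with f_r ≥ f_d) are
controlled by Benjamini–Hochberg FDR across each cohort, giving the
occurrence frequency f_p of significant fencing. Downstream analyses relate
per-patient FPM to outcomes: two-sample t-tests, Pearson correlation with
response codes, a density/FPM combination c(r), uncorrected Ripley's
K-cross comparisons, and a cohort-mean FPM split compared by log-rank test.

**Mechanistic models.** A continuous-time random walk on a lattice
(a = 10 μm, D = 2.5 μm²/min, periodic width L = 230 μm, absorbing tumor
boundary) quantifies how a reflecting fence of length b cuts the *tumor
access ratio* R_b(T) = (boundary arrivals with fence)/(arrivals without)
within horizon T; the no-fence arrival probability from height y0 is the
image-method closed form erfc(y0/√(4DT)). A chemotaxis variant adds a
near-boundary drift v(b) = 5·min(b, 150)/150 μm/min that grows with fence
length. A kinetic Monte Carlo interacting-cell-system (ICS) model of
tumor / CD8 / macrophage agents on a 100×100 chamber lattice measures the
population-level effect of implanting impenetrable ~50 μm fences at
20 per mm².

All pipelines run on synthetic slides with planted ground truth
(`tumorfence.synthetic`), so nothing requires patient data.

## Worked example

```python
from tumorfence.synthetic import SyntheticSlideConfig, generate_slide
from tumorfence.fencing import find_fencing
from tumorfence.null_model import fencing_pvalue, compute_fpm
from tumorfence.boundary_access import LatticeConfig, tumor_access_ratio

cfg = SyntheticSlideConfig()          # 20 planted fences, ~50 um, on the tumor rim
slide = generate_slide(cfg, seed=1)
print(f"slide: {len(slide)} cells ({slide.n_tumor} tumor, {slide.n_phenotype('g')} g)")

res = find_fencing(slide, "g")
print(f"clusters: {len(res.clusters)}, fencing: {len(res.fencing_clusters)}, f_d = {res.f_d}")

f_d, ens, p = fencing_pvalue(slide, "g", n_perm=1000, seed=0)
print(f"permutation null: <f_r> = {ens.mean_f_r:.1f}, p = {p:.3f}, "
      f"FPM = {compute_fpm(f_d, ens.mean_f_r):.3f}")

r = tumor_access_ratio(LatticeConfig(), [70.0], [3600.0], seed=0, S=500)[0]
print(f"70 um fence, T = 2.5 d: R_b = {r.ratio:.3f} "
      f"({100*(1-r.ratio):.1f}% access reduction)")
```

prints

```
slide: 1345 cells (476 tumor, 377 g)
clusters: 26, fencing: 8, f_d = 184
permutation null: <f_r> = 101.1, p = 0.000, FPM = 0.451
70 um fence, T = 2.5 d: R_b = 0.846 (15.4% access reduction)
```

Of the slide's 377 g-cells, 184 sit in the eight clusters that hug the
tumor boundary; random relabeling places only ~101 there, so the planted
fencing is far beyond chance (p < 1/1000) with FPM 0.45. On the lattice, a
70 μm fence removes about 15 % of cytotoxic-cell arrivals over 2.5 days.

The same workflows are scriptable from a shell:

```sh
tumorfence synth --out cohort/ --n-per-group 10 --seed 1
tumorfence fence --slides cohort/ --out fpm/ --n-perm 1000 --seed 1
tumorfence associate --fpm fpm/fpm.csv --outcomes cohort/outcomes.csv --mode survival --out surv/
tumorfence minimal --model chemotaxis --out chemo/ --b 0 --b 50 --b 100 --horizon 720
```

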