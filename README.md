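# circamoran

Spatial autocorrelation analysis for oscillatory imaging data: Moran's *I*,
its circular variant *I*<sub>θ</sub> for instantaneous phases, Monte-Carlo
significance testing, Hilbert-transform phase extraction, the Kuramoto order
parameter, and a lattice Kuramoto simulator for synthetic benchmarks.

## Why

Synchronization in spatially extended oscillator ensembles — the canonical
example here being circadian PER2::LUC bioluminescence recorded across the
suprachiasmatic nucleus (SCN) — is usually summarised by the Kuramoto order
parameter

$$R(t)\,e^{i\psi(t)} = \frac{1}{N}\sum_{j=1}^{N} e^{i\theta_j(t)},$$

which treats all units as interchangeable and therefore ignores *where* they
are. A phase wave, a spiral, or two anti-phase regional clusters can all have
low *R* despite being highly organised in space. Moran's *I*,

$$I = \frac{\sum_{ij} w_{ij}(X_i-\bar X)(X_j-\bar X)\big/\sum_{ij} w_{ij}}
         {\frac{1}{N}\sum_i (X_i-\bar X)^2},$$

measures exactly that missing ingredient: the ratio of neighbourhood-weighted
covariance (local coherence, with the neighbourhood prescribed by a spatial
weight matrix $w_{ij}$) to total variance. It is near +1 for locally coherent
fields, −1 for locally alternating fields, and $-1/(N-1)$ in expectation for
random ones. For circular variates such as instantaneous phases
$\theta_i \in (-\pi, \pi]$, arithmetic deviations are replaced by signed
shortest angular displacements from the circular mean,
$d_\theta(X_i, \bar X) = \mathrm{atan2}(\sin(X_i-\bar X), \cos(X_i-\bar X))$,
giving the circular index *I*<sub>θ</sub>. Read together, $(I_\theta, R)$
separate states that either measure alone confuses.

## Worked example

```python
import circamoran as cm

# a strictly alternating 10x10 checkerboard under range-1 von Neumann weights
W = cm.grid_von_neumann_weights(10, 10, 1)
field = cm.binary_grid(10, 10, "checkerboard")
print("checkerboard I =", cm.morans_i(field, W).statistic)

# a phase spiral: low global coherence, strong spatial order
spiral = cm.phase_pattern(25, 25, "spiral")
W25 = cm.grid_von_neumann_weights(25, 25, 1)
R, _ = cm.kuramoto_order(spiral.phases)
I_theta = cm.morans_i_circular(spiral, W25).statistic
null = cm.null_distribution(spiral, W25, mode="randomize", n_samples=10_000, seed=1)
lo, hi = cm.critical_band(null, alpha=0.05)
print(f"spiral: R = {R:.3f}, I_theta = {I_theta:.3f}, "
      f"95% null band = [{lo:.3f}, {hi:.3f}], p = {cm.p_value(I_theta, null):.2e}")
```

prints

```
checkerboard I = -1.0
spiral: R = 0.050, I_theta = 0.882, 95% null band = [-0.056, 0.056], p = 2.00e-04
```

The checkerboard is the most locally alternating binary pattern, hence
exactly −1. The spiral has phases arranged radially over their whole
co-domain, so the mean phasor nearly cancels (*R* = 0.05) — yet neighbouring
cells carry very similar phases, which *I*<sub>θ</sub> = 0.88 detects far
outside the randomization null band.

A full pipeline — simulate a 25×25 nearest-neighbour Kuramoto lattice,
extract phases, test against the null — is also available from the shell:

```sh
circamoran simulate --rows 25 --cols 25 -K 0.1 --seed 3 --out sim.tsv
circamoran fixtures movie --rows 10 --cols 10 --kind two_cluster --out movie.tsv
circamoran detrend movie.tsv --out detrended.tsv
circamoran phases detrended.tsv --out phase.tsv
```

See `circamoran --help` for the remaining subcommands (`moran`,
`moran-phase`, `null`, `order`, `correlogram`).

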