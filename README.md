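# abclock

Quantitative analysis of how cell division and abscission time the exit
of mouse embryonic stem (ES) cells from naive pluripotency.

When the pluripotency-promoting medium (2i/LIF) is withdrawn at t = 0,
each cell's naive-state reporter (a destabilized GFP knocked into the
*Rex1* locus) decays sigmoidally, and the decay is gated by cell
division: cells triggered early in their cycle exit after the first
division, cells triggered late exit after the second. Sister cells —
which stay connected by a microtubule-filled intercellular bridge long
after cytokinesis, exchanging cytoplasm until abscission — exit with
strikingly similar dynamics. `abclock` implements the statistics that
quantify each link in this chain, for anyone analyzing single-cell
time-lapse reporter tables, bridge-width time courses or FRAP traces:

- **Exit-time estimation** — least-squares fit of the logistic decay
  `I(t) = lo + (hi − lo) / (1 + e^((t−τ)/k))`; the exit time τ is the
  curve's inflection, with a quality filter discarding cells whose fit
  error on τ is of the order of τ itself.
- **Division–exit coupling** — each cell's τ is paired with its latest
  division (the largest division time ≤ τ + 2.5 h); the regression R²
  of τ on division time is tested against a reassignment bootstrap null
  (τ of cell *i* re-paired with the divisions of a random cell *j*,
  with replacement, 1000 replicates; one-sided empirical p).
- **Sister statistics** — time-averaged population ("global") versus
  within-sister-pair ("local") variance of first-point-normalized
  curves; |Δτ| for sister versus random pairs; correlation of the
  division asymmetry ratio (smaller/larger daughter volume) with exit
  outcomes.
- **Bridge kinetics** — exponential thinning
  `w(t) = w_∞ + (w_0 − w_∞) e^(−t/τ_c)` fitted per bridge; conditions
  compared by an extra-sum-of-squares F test (shared versus separate
  τ_c) or a label-permutation test; abscission-duration summaries and
  per-frame bridge fractions.
- **FRAP exchange** — two-compartment model
  `dc_b/dt = k(c_s − c_b)`, trailing 4-point smoothing, pre-bleach
  normalization, and the post-bleach minimum as the transfer readout.
- **Synthetic data** — generators for every stream above, with defaults
  calibrated to the published measurements (bridge τ_c of 45 min in
  naive versus 15 min in exiting cells, abscission durations of
  8.2 ± 3.8 h in naive ES versus 1.5 ± 0.5 h in HeLa cells, coupling
  R² ≈ 0.73), emitting ground-truth columns for recovery tests.

## Worked example

```python
from abclock import SimConfig, simulate_lineage, bootstrap_null
from abclock.trajectory import fit_table
from abclock.coupling import pairs_from_tables

lineage, traj = simulate_lineage(SimConfig(seed=1))   # 30 families
fits = fit_table(traj)                                # sigmoid fits + filter
pairs = pairs_from_tables(fits, lineage)
res = bootstrap_null(pairs, n_boot=1000, seed=1)
print(f"R^2 = {res.r_squared:.3f}, p_empirical = {res.p_empirical:.3f}")
```

This prints:

```
R^2 = 0.673, p_empirical = 0.000
```

60 of 60 synthetic cells pass the fit filter; the regression of exit
time on latest division time gives R² = 0.673 (unit slope — exit tracks
division plus a lag), and none of the 1000 reassignment replicates
reaches the observed R², so the coupling would essentially never arise
by chance under the null.

The same stages are scriptable from the shell:

```sh
abclock simulate lineage --seed 1 --out data/
abclock fit-rex1 --in data/trajectories.tsv --out data/fits.tsv
abclock coupling --fits data/fits.tsv --lineage data/lineage.tsv --n-boot 1000
abclock run --config run.yaml --seed 1 --out results/   # end-to-end
```

All tables are TSV with unit-suffixed columns (`t_h`, `t_min`, `t_s`,
`width_um`, `intensity_au`) distinguishing the pipeline's three clocks:
hours from 2i/LIF removal, minutes from cytokinesis end, seconds from
the bleach pulse.

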