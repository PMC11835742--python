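# neuroturb

Whole-brain **turbulence dynamics** for parcellated resting-state BOLD:
model-free information-flow measures built on the local Kuramoto order
parameter, a Stuart–Landau (Hopf) whole-brain model with exponential-distance
coupling, in-silico perturbation readouts, permutation-based group inference,
and a treatment-response classifier. The package ships a synthetic-cohort
generator, so the entire analysis runs and is tested end to end without any
external data.

It is aimed at computational-neuroscience practitioners who want to
characterize spatiotemporal synchronization structure in clinical fMRI
cohorts — for example, to ask whether baseline brain dynamics carry
information about antidepressant treatment response.

## The measures

Given band-passed (0.008–0.08 Hz) regional BOLD with Hilbert phases
φ<sub>k</sub>(t), the **local Kuramoto order parameter** at inverse-distance
scale λ (per mm) is

    R_j(t) e^{iθ_j(t)} = Σ_k w_jk e^{iφ_k(t)} / Σ_k w_jk,   w_jk = e^{−λ d_jk}

where d<sub>jk</sub> is the Euclidean distance between region centroids. The
characteristic probe length is 1/λ: λ = 0.01 looks ~100 mm across the brain,
λ = 0.3 at ~3.3 mm neighborhoods. From R the package derives:

- **amplitude turbulence** D — sample SD of R over space and time (the
  vortex-like variability of local synchronization);
- **node-level metastability** — per-region SD of R over time;
- **information cascade flow** — lag-1 correlation of R between adjacent
  scales, and its scale-average, the **information cascade**;
- **information transfer** — the log–log decay slope of the spatial
  correlation of R with inter-region distance.

The model-based arm couples Stuart–Landau oscillators (bifurcation parameter
`a`, intrinsic frequencies ω<sub>j</sub>) through an exponential-distance-rule
connectome with long-range exceptions, scaled by a global coupling `G` fitted
by matching functional connectivity as a function of distance. Perturbing the
fitted model's bifurcation parameters in silico yields **susceptibility**
(trial-mean absolute shift of the mean local order parameter) and
**information encoding capability** (trial SD of that shift).

## Worked example

```python
import numpy as np
import neuroturb as nt

geom = nt.generate_geometry(60, seed=1)                     # synthetic parcels
connectome = nt.generate_connectome(geom, n_longrange=40, seed=2)
spec = nt.CohortSpec(n_regions=60, n_volumes=300, tr=2.0,
                     group_sizes=(20, 20, 20), group_G=(1.3, 1.5, 0.9),
                     outcome_correlation=0.4, seed=7)
cohort = nt.generate_cohort(spec, geom, connectome)

profiles = {r.subject_id: nt.compute_profile(r.bold, geom) for r in cohort}
resp = [profiles[r.subject_id].at_scale(profiles[r.subject_id].turbulence, 0.01)
        for r in cohort if r.group == "responder"]
nonresp = [profiles[r.subject_id].at_scale(profiles[r.subject_id].turbulence, 0.01)
           for r in cohort if r.group == "non_responder"]
print("turbulence(lam=0.01):",
      f"responders {np.mean(resp):.4f}, non-responders {np.mean(nonresp):.4f}")
print("Cohen's d:", round(nt.cohens_d(resp, nonresp), 2),
      " p:", nt.perm_ranksum(resp, nonresp, n_perm=1000, seed=0))
```

prints

```
turbulence(lam=0.01): responders 0.1950, non-responders 0.1720
Cohen's d: 1.12  p: 0.001998001998001998
```

i.e. the group simulated at higher global coupling (the responder-like group)
shows higher amplitude turbulence at the largest spatial scale, the
permutation rank-sum test detects the difference (p = 2/1001, near the
add-one floor of the 1000-permutation test), and the effect size is large. A classifier on the seven baseline
features (turbulence and information transfer at λ ∈ {0.01, 0.03, 0.06} plus
the information cascade) separates responders from non-responders well above
chance (`nt.repeated_split_eval`, balanced RBF-SVM with repeated 90/10
splits).

The same pipeline is scriptable from the shell:

```bash
neuroturb demo --out-dir demo_out --seed 1        # synth + measures + stats + classify
neuroturb demo --with-model --out-dir demo_out    # ... + G fit + perturbation
```

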