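# eegconn

Multi-metric functional connectivity for region-level (source-space) EEG.

Single connectivity metrics disagree: coherence, phase locking and mutual
information each see a different slice of the dependence between two brain
regions, and zero-lag measures are confounded by volume conduction while
lagged measures are blind to it.  `eegconn` takes the integrationist route:
it computes **101 connectivity configurations** per region pair — four
frequency-domain families (linear connectivity *F*, coherence ρ², nonlinear
connectivity *G*, phase synchronization φ²), each split into instantaneous,
lagged and total parts across eight bands (δ, θ, α1, α2, β1, β2, β3, γ),
plus five broadband time-domain measures (Pearson ρ, Gaussian-copula MI,
conditional MI, symbol-weighted MI, O-information) — then selects
group-discriminative edges with permutation tests under per-configuration
BH-FDR, maps hypo-/hyperconnectivity consistency across metrics, and
classifies patients vs controls with a tuned gradient-boosted model,
progressive feature inclusion and TreeSHAP attributions.

The frequency-domain core is the log-determinant decomposition of the band
cross-spectrum S:

    F_total  = ln(|Sxx||Syy| / |S|)
    F_inst   = ln(|Re Sxx||Re Syy| / |Re S|)
    F_lagged = F_total − F_inst
    ρ²       = 1 − exp(−F)        (coherence-type mapping, in [0, 1])

with nLC/PS applying the same forms to amplitude-normalized Fourier
coefficients.  On univariate region series this reduces to |c|², Re(c)² and
Im(c)²/(1 − Re(c)²) for the complex coherency c.

It is aimed at researchers who have region-level source time series (e.g.
from an inverse solution averaged within an atlas parcellation — an
82-region AAL table ships with the package) and want a tested,
reproducible multi-metric pipeline.  A synthetic cohort generator with
planted, band-specific group differences makes every stage testable without
any recording.

## Worked example

```python
import eegconn as e
from eegconn.pipeline import default_couplings

# two groups of 10 subjects, 16 regions, 256 Hz, 60 s, with planted
# band-specific couplings (hypo = present in controls only, hyper = in
# patients only) and broadband covariance effects
cfg = e.RunConfig(couplings=default_couplings(), seed=3)
subjects, truth = e.generate_cohort(cfg.cohort_spec())

tensor = e.connectivity_tensor(subjects)          # 101 configs x 120 pairs
results = e.select_edges(tensor, n_perm=5000, seed=3)
table = e.build_consistency(results, tensor.n_regions)
print(table.pair_counts.query("hypo + hyper >= 5"))

survivors = [r for r in results if r.passes_fdr]
fm = e.assemble_features(tensor, survivors,
                         "complementary_frequency", family="Coh")
report, model = e.train_and_evaluate(fm, seed=0)
mean_f1, lo, hi = report.scores["f1"]
print(f"CV F1 {mean_f1:.2f} (95% CI {lo:.2f}-{hi:.2f}), "
      f"test F1 {report.test_scores['f1']:.2f}")
```

Output:

```
     region_a  region_b  hypo  hyper
0           0         1     8      0
29          2         3     8      0
54          4         5     8      0
75          6         7     0      9
92          8         9     0      8
105        10        11    20      0
114        12        13     0     20
CV F1 0.96 (95% CI 0.88-1.04), test F1 1.00
```

The consistency table recovers exactly the seven planted pairs: the five
band couplings are flagged by 8–9 configurations each (the lagged and
total variants of the four spectral families), the two broadband
covariance effects by 20 (time-domain metrics plus instantaneous spectral
variants), with the planted direction.  The classifier built from the
coherence-family survivors reaches a cross-validated F1 of 0.96
(95% CI 0.88–1.04, CI overshooting 1 is the normal-approximation artifact
of fold-wise CIs) and test-set F1 of 1.0 on this separable cohort.

A command-line interface chains the same stages
(`eegconn simulate | connectivity | select | classify | run`); see
`eegconn --help`.

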