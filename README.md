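# cboost — concordance-index boosting for survival data

`cboost` derives and evaluates **linear biomarker combinations for
censored time-to-event outcomes** using a single criterion throughout:
the concordance index (C-index).  It is aimed at biostatisticians and
bioinformaticians building prognostic signatures (e.g. gene-expression
panels for time to metastasis) who want the quantity they optimise to be
the quantity they report.

Deriving a signature involves three tasks, and mixing criteria between
them — screening by p-values, fitting by Cox partial likelihood,
reporting a C-index — yields combinations that are suboptimal for the
reported measure.  `cboost` uses the C-index for all three:

1. **Pre-selection** — rank candidate markers by their univariate IPCW
   concordance and keep the top few (`preselect`).
2. **Estimation** — fit a sparse linear combination
   `η = x'β` by component-wise gradient boosting of a smoothed C-index
   (`boost_cindex`).
3. **Evaluation** — score the combination on held-out data with Uno's
   unsmoothed IPCW estimator (`evaluate_on_test`, `subsample_evaluate`).

## The statistic and the algorithm

For a predictor `η` and survival time `T`, the concordance index is
`C = P(η_j > η_i | T_j > T_i)` — the probability that of two random
subjects, the one predicted to live longer does (0.5 = chance, 1 =
perfect).  With right-censored observations `(T̃_i, Δ_i)`, Uno's
estimator weights each usable ordered pair (`T̃_j < T̃_i`, `Δ_j = 1`) by
`Ĝ(T̃_j−)^{-2}`, the inverse squared Kaplan-Meier estimate of the
censoring survival function, which removes the censoring bias of
Harrell's unweighted pair count.

The estimation step maximises a differentiable surrogate in which the
hard ordering indicator is replaced by a sigmoid with scale `σ`
(default 0.1):

    R(η) = − Σ w_pair · sig((η_i − η_j)/σ) / Σ w_pair

Component-wise boosting minimises `R`: per iteration, one simple linear
base-learner per marker is fitted to the negative gradient, only the best
one (least squares) updates its coefficient by a small step (default
0.1), yielding intrinsic variable selection and a deterministic, sparse
linear combination.  See `docs/methods.md` for the full model and design
choices.

## Worked example

`examples/02_derive_signature.py` runs the full workflow on synthetic
data from the package's four-marker log-logistic AFT design (50
correlated candidate markers, 4 informative, 50% censoring):

```
Task 1 - selected markers: ['x1', 'x2', 'x3', 'x4', 'x39']
         univariate scores: [0.586 0.573 0.564 0.558 0.514]
         (truly informative: x1..x4)
Task 2 - boosted coefficients (standardized scale): {'x1': 0.26, 'x2': 0.11, 'x3': -0.2, 'x4': -0.21, 'x39': -0.03}
Task 3 - test concordance 0.750 vs apparent 0.775
```

Task 1 found all four informative markers (plus one noise marker, scored
near chance at 0.514).  Task 2 recovered the true effect structure — two
positive, two negative, the outer effects strongest, the noise marker
near zero.  Task 3's test concordance of 0.750 is the honest estimate of
discriminatory power: this signature correctly orders about three of
four comparable patient pairs on new data, while the apparent
(training-sample) value of 0.775 is optimistic.  The true
data-generating combination achieves ≈0.779 under the same protocol, so
estimation from n=100 costs about 0.02–0.03 in concordance.

The other example scripts cover the estimator comparison under censoring
(`01`), a reduced run of the full benchmark grid (`03`) and stratified
subsampling evaluation on a single dataset (`04`).  A thin CLI wraps the
same functions: `cboost-surv simulate|preselect|fit|evaluate|subsample-eval|simstudy`.

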