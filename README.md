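# equigof

Equivalence tests of **goodness** — rather than lack — of fit for continuous
distributions.

## Why

Classical goodness-of-fit procedures (Kolmogorov–Smirnov, chi-square, …)
place model correctness in the *null* hypothesis.  A significant result
therefore demonstrates lack of fit, while the outcome practitioners usually
want — evidence that the model *does* fit — can never be established that
way: non-rejection is not proof.  `equigof` inverts the logic.  Closeness of
the true distribution F to a hypothesized continuous model F₀ becomes the
*alternative* hypothesis, so a significant result positively establishes
approximate fit at significance level α.

Closeness is parametrized through **Lehmann alternatives**: the indifference
zone around F₀ consists of all cdfs F = F₀^θ with θ in a narrow interval
around 1 (θ is a hazard-ratio analogue on the cdf scale).  The testing
problem is

    H: θ ≤ 1/(1+ε)  or  θ ≥ 1+ε      vs.     K: 1/(1+ε) < θ < 1+ε,

and the margin ε is in one-to-one correspondence with a bound δ on the
Kolmogorov distance ‖F − F₀‖ via (1+ε)^(−1/ε) − (1+ε)^(−(1+ε)/ε) = δ
(for example δ = 0.15 ↔ ε = 0.5077).

## What is implemented

- **margins** — exact translation δ ↔ ε between the sup-distance and
  Lehmann-parameter margins.
- **lehmann** — the model F = F₀^θ: a catalogue of F₀ (normal, exponential,
  uniform, logistic, user callables), inverse-transform sampling, the ML
  estimator θ̂ₙ = −n/Σᵢ log F₀(Xᵢ) and its exact distribution-free law
  (2θn/θ̂ₙ is chi-square with 2n df).
- **ump_test** — the exact *uniformly most powerful* level-α test of H vs K:
  reject (establish fit) iff C₁ < θ̂ₙ < C₂, with (C₁, C₂) solved from the
  two boundary-size equations on the chi-square scale; exact power and
  smallest-n search.
- **grouped_test** — the multinomial counterpart on k equal-probability
  classes: induced Euclidean-distance margin ε\*, the asymptotic
  equivalence test on class frequencies, and exact/Monte-Carlo power
  (grouping loses substantial efficiency versus the exact test).
- **score_test** — when the model is a whole location-scale *family*
  F₀((·−μ)/σ) with unknown (μ, σ): double one-sided (TOST) efficient-score
  tests at the two boundary θ values, with restricted MLEs for (μ, σ) and
  variances from the quadrature-computed expected information matrix.
- **cli_io** — file readers (txt/CSV/XLSX), fixture generation, JSON/text
  reports and the `equigof` command-line tool.

## Worked example

Simulate 100 observations from a standard normal (so the model truly fits),
then test goodness-of-fit of the standard normal with margin δ = 0.15:

```console
$ equigof margin --delta 0.15
delta      0.1500
epsilon    0.5077
log(1+eps) 0.4106

$ equigof --seed 1729 simulate -n 100 --theta 1.0 --out demo.txt
wrote demo.txt (n=100)

$ equigof ump-test --data demo.txt --epsilon 0.5077
n                 100
theta_hat         0.9595
critical interval (0.7883, 1.2887)
decision          goodness-of-fit established (null hypothesis of lack-of-fit rejected)
```

θ̂ = 0.9595 lies inside the critical interval (0.7883, 1.2887), so standard
normality is positively established at α = 0.05 within the δ = 0.15 band —
the exit status is 0.  Testing the weaker statement that the data are normal
with *some* (μ, σ) is much harder; the score test refuses it at this sample
size:

```console
$ equigof score-test --data demo.txt --epsilon 0.5077
restricted fit, lower: mu=0.2868 sigma=0.8784
restricted fit, upper: mu=-0.4502 sigma=1.1077
U(lower)=2.1426  z=1.674707  reject one-sided: True
U(upper)=0.5176  z=0.983458  reject one-sided: False
decision       goodness-of-fit NOT established (lack-of-fit null not rejected)
```

Only the lower one-sided hypothesis is rejected (z = 1.6747 > z₀.₉₅ =
1.6449); the upper one is not (0.9835 > −1.6449), so the TOST combination
fails — establishing fit of a location-scale family needs far larger n.

Other entry points: `equigof ump-power`, `equigof ump-size`,
`equigof grouped-test`, `equigof tables --which 1|2`, and the library API
(`import equigof`).

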