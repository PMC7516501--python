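# pyinar

Semi-parametric Bayesian modelling of count time series: an INAR(p)
(integer-valued autoregressive) model whose Poisson innovation rates are
clustered by a Pitman–Yor process prior — the **PY-INAR(p)** model — with
a data-augmented Gibbs sampler, principled prior elicitation, posterior
clustering of time epochs, and one-step-ahead forecasting.

It is aimed at analysts of epidemic case counts, event tallies
(e.g. yearly strong-earthquake counts), and similar non-negative integer
series in which the rate of new arrivals shifts between latent regimes.

## Model

The observation equation is the INAR(p) functional relation

    Y_t = α₁ ∘ Y_{t−1} + ⋯ + α_p ∘ Y_{t−p} + Z_t,   Z_t ~ Poisson(λ_t),

where `α ∘ Y` is binomial thinning (each of the Y previous cases survives
independently with probability α). Instead of a single innovation rate,
the rates λ_{p+1}, …, λ_T are drawn from a random measure G ~ PY(τ, σ,
Gamma(a₀, b₀)): the Pitman–Yor process with concentration τ, discount σ,
and a Gamma base measure. Discreteness of G ties the rates into clusters
of epochs sharing one innovation regime; the number of clusters K is
inferred. The thinning vector has a Dirichlet prior supported on the
non-explosive simplex Σα_i < 1.

Hyperparameters are set by elicitation: τ solves E[K] = k₀ for a chosen
prior cluster count k₀, and (a₀, b₀) minimize the KL divergence to a
Uniform[0, λmax] reference, with λmax chosen where the posterior expected
cluster count E[K | y] levels off along a scanned grid (the sensitivity
"elbow" criterion). See `docs/methods.md` for the full account.

## Worked example

Simulate the reference design — INAR(1) with thinning 0.15, T = 1000, and
innovations from an equal-weight mixture of Poisson(1), Poisson(8),
Poisson(15) — then recover the three innovation regimes:

    $ pyinar simulate --output-dir demo --seed 1
    wrote series.csv, true_rates.csv, true_components.csv to demo

    $ pyinar cluster -i demo/series.csv --output-dir demo \
          --k0 10 --sigma 0.75 --lambda-max 300 --n-clusters 3 \
          --iters 2000 --burn 600 --seed 1 \
          --truth demo/true_components.csv
    confusion matrix written; accuracy = 0.845
    cut at 3 clusters

The pipeline behind those two lines: fit the PY-INAR(1) model by Gibbs
sampling; estimate the co-clustering dissimilarities d_rt = Pr{λ_r ≠ λ_t
| y} from the retained draws; embed the 999 epochs in the plane by
classical multidimensional scaling; cut a Ward dendrogram at 3 clusters;
and match predicted clusters to the true mixture components. The written
`confusion.csv` (rows: predicted cluster, columns: true component):

    314,18,1
    25,257,65
    0,46,273

i.e. 844 of 999 innovations (84.5%) are assigned to the regime that
actually generated them; the errors concentrate between the two
high-rate regimes (8 vs 15), whose Poisson distributions overlap. Omit
`--lambda-max` to let the elbow scan choose the base-measure scale, and
use `pyinar elbow` to export the E[K | y] curve itself. `pyinar forecast
--model both` compares one-step-ahead MAE of PY-INAR against the
homogeneous INAR baseline by rolling-origin cross-validation.

The same functionality is available as a library (`pyinar.run_gibbs`,
`pyinar.elbow_scan`, `pyinar.cluster_point_estimate`,
`pyinar.rolling_cv`, …); every command writes plain CSV plus a JSON
manifest (seed, config, input hash) from which its outputs are exactly
reproducible.

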