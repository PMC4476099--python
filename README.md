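# gexsens

Global sensitivity analysis of a dynamic reaction–diffusion model of gene
expression in the early *Drosophila* embryo.

## The scientific problem

In the syncytial blastoderm stage of *Drosophila* development, nuclei share a
common cytoplasm, so mRNA and protein both react (transcription, translation,
decay) and diffuse between neighbouring nuclear territories. A long-standing
question is which process — transcription or translation — contributes more
to the variance in protein levels. This package approaches the question with
a mechanistic model and variance-based global sensitivity analysis, for
modellers who want to compare parameter sensitivities against experimentally
measured contribution-to-variance estimates from mammalian cells.

## The model

A single gene with spatially uniform transcription in a 1-D chain of *n*
nuclei (default *n* = 52). Writing *m_i* and *p_i* for mRNA and protein in
nucleus *i*, for interior nuclei

```
dm_i/dt = σ + d (m_{i+1} − 2 m_i + m_{i−1}) − λ m_i
dp_i/dt = τ m_i + δ (p_{i+1} − 2 p_i + p_{i−1}) − γ p_i
```

with zero-flux boundaries (end nuclei couple to a single neighbour). The six
rates are σ (transcription), d (mRNA diffusion), λ (mRNA decay),
τ (translation), δ (protein diffusion), γ (protein decay), all per minute.
Trajectories are integrated with fixed-step RK4 (dt = 0.01 min).

Sensitivities come from a High Dimensional Model Representation (HDMR) of a
scalar output f (protein at a chosen nucleus and time) over a 6-D parameter
hypercube sampled with a Sobol low-discrepancy design:

```
f(x) = f₀ + Σᵢ fᵢ(xᵢ) + Σ_{i<j} f_ij(xᵢ, xⱼ) + …
```

Component functions are fitted in orthonormal shifted-Legendre bases; their
variances, normalized by the total output variance, give the first-order
indices S_i and second-order indices S_ij. A parameter-range exploration
procedure (screening simulated protein for saturation ≥ 7 or undetectable
≤ 0.01 levels) defines the "realistic" hypercube; the published ranges ship
as `gexsens.TABLE1_SPACE`.

## Worked example

Decompose the protein concentration at the middle nucleus at t = 4 min for a
gene expressed ubiquitously with initial mRNA and protein levels of 1.0:

```python
import gexsens as g

design = g.SobolDesign.generate(1024, g.TABLE1_SPACE)
outputs = g.evaluate_objective_batch(
    design,
    g.InitialConditionSpec("ubiquitous", 1.0),
    g.ObjectiveSpec("middle_nucleus", 4.0),
)
result = g.hdmr_decompose(design, outputs, g.HDMRConfig(n_samples=1024))
print(result.summary())
```

prints

```
HDMR variance decomposition
  samples: 1024   polynomial order: 3
  f0 (mean output):   1.83874
  total variance D:   1.99404

  parameter      S_i  sum S_ij   total
  sigma        0.319     0.094   0.413
  d            0.000     0.000   0.000
  lam          0.165     0.060   0.224
  tau          0.309     0.104   0.413
  delta        0.000     0.000   0.000
  gamma        0.052     0.015   0.067

  sum first-order:          0.844
  sum second-order:         0.136
  first + second order:     0.981
```

Transcription (σ) and translation (τ) each explain ≈ 32% of the output
variance, mRNA decay (λ) ≈ 17%, protein decay (γ) ≈ 5%; diffusion is inert
for a spatially uniform initial condition, so d and δ are exactly 0. First-
order terms dominate (≈ 0.84 of ≈ 0.98 captured variance), and

```python
print(g.compare_to_reference(result.first_order))
# ComparisonResult(pearson_r=0.9671114387784273, max_abs_diff=0.087968671057452)
```

shows the close agreement with the experimentally measured contributions to
protein-level variance in mammalian cells (transcription 38%, mRNA decay
18%, translation 30%, protein decay 14%).

The same analysis is available from the shell:

```
gexsens hdmr --ic ubiquitous --level 1.0 --objective middle_nucleus \
    --time 4 --n 8192 --out hdmr.json
gexsens full-analysis --n 8192 --out results/   # the whole 5×4×11 grid
gexsens simulate --ic anterior --sigma 1 --d 0.5 --lam 0.4 --tau 0.5 \
    --delta 0.5 --gamma 0.6 --t-end 20 --out traj.csv
gexsens explore --config explore.yaml --out space.json
```

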