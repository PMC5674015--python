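"""Score nuclear hypertrophy along a principal-curve morphologic continuum.

Simulates nuclei whose (area, eccentricity, perimeter)-like features lie on
a 1-D continuum f_i = g(lambda_i) + noise with a Gamma(4) latent, fits a
principal curve anchored by a normal-appearing and a hypertrophic nucleus,
scores every nucleus by its path length s_i from the curve origin, and
summarizes the population with the hypertrophy index HI (negated skewness
of the scores). The Gamma(4) latent itself has skewness 2/sqrt(4) = 1; the
path-length scores are a convex transform of it, so their skew — and hence
|HI| — comes out somewhat larger.
"""

from scipy.stats import spearmanr

from histolearn import (
    SimConfig,
    fit_principal_curve,
    hypertrophy_index,
    score_hypertrophy,
    simulate_hypertrophy_population,
)

pop = simulate_hypertrophy_population(SimConfig(seed=2))
print(f"population: {len(pop.latent)} nuclei, noise sigma {pop.noise_sigma}")

curve = fit_principal_curve(pop.features, pop.anchors)
print(f"fitted curve: {len(curve.vertices)} vertices, "
      f"total length {curve.total_length:.2f} (standardized units)")

scores = score_hypertrophy(curve, pop.features)
rho = spearmanr(scores.scores, pop.latent).statistic
hi = hypertrophy_index(scores)
print(f"Spearman(path length, true latent) = {rho:.3f}")
print(f"hypertrophy index HI = {hi:.3f}")
print(
    "\nScores track the hidden morphologic continuum almost perfectly "
    f"(rho {rho:.3f}); the negative HI ({hi:.2f}) reflects the "
    "right-skewed score distribution: most nuclei sit near the normal end "
    "with a long tail of hypertrophic ones."
)
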