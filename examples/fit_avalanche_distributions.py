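"""Fit a truncated power law and a truncated log-normal to avalanche sizes.

Reproduces the model-selection step of the criticality-assessment
methodology: both distributions are fit by maximum likelihood on the integer
support [smallest observed value, cutoff], and the power law "passes" when
its AIC does not exceed the log-normal's.  A negative delta-AIC favors the
power law.
"""

from avacrit import (
    SurrogateParams,
    bin_spikes,
    compare_aic,
    default_bin_width,
    extract_avalanches,
    fit_truncated_lognormal,
    fit_truncated_powerlaw,
    simulate_surrogate,
)

raster = simulate_surrogate(SurrogateParams(), 60_000.0, seed=3)
av = extract_avalanches(bin_spikes(raster, default_bin_width(raster)))
sizes = av.sizes

for s_max in (15, 50, 150):
    x_min = int(sizes[sizes <= s_max].min())
    pl = fit_truncated_powerlaw(sizes, x_min, s_max)
    ln = fit_truncated_lognormal(sizes, x_min, s_max)
    verdict = compare_aic(pl, ln)
    print(
        f"sizes on [{x_min}, {s_max}]: tau = {pl.exponent:.3f}, "
        f"lognormal (mu, sigma) = ({ln.mu:.2f}, {ln.sigma:.2f}), "
        f"delta AIC = {verdict.delta_aic:+.1f} -> "
        f"{'power law passes' if verdict.passes else 'log-normal preferred'}"
    )
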