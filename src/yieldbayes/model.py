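"""Model/Results interface tying the pipeline stages together.

:class:`TwoGroupYieldModel` wraps a measurement table holding test and control
yields; ``fit()`` runs the per-group MCMC and the contrast computation and
returns a :class:`TwoGroupYieldResults` carrying the posteriors, the effect
summaries and a text ``summary()`` table, in the style of statsmodels model /
results pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as ybio
from .contrast import ContrastResult, compute_contrast
from .mcmc import GroupPosterior, SamplerConfig, fit_group
from .preprocessing import three_sigma_filter, stratified_balance_sample
from .simulate import CONTROL, TEST, SimulationConfig, simulate_measurements


class TwoGroupYieldModel:
    """Bayesian two-group comparison of polygon-level dry yields.

    Parameters
    ----------
    data : measurement table with columns
        ``field_id, group, x, y, area_m2, dry_yield_kg_ha`` where ``group`` is
        ``"test"`` (treated) or ``"control"``.
    location : label carried through to reports.
    """

    def __init__(self, data: pd.DataFrame, location: str = ""):
        self.data = ybio.validate_measurements(data).reset_index(drop=True)
        self.location = location
        for g in (TEST, CONTROL):
            if (self.data["group"] == g).sum() < 2:
                raise ValueError(f"need >= 2 measurements in group {g!r}")
        self.filter_reports = None
        self.sampling_plan = None

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_csv(cls, path, location: str = "") -> "TwoGroupYieldModel":
        return cls(ybio.read_csv(path), location=location)

    @classmethod
    def from_geojson(cls, path, location: str = "") -> "TwoGroupYieldModel":
        return cls(ybio.read_geojson(path), location=location)

    @classmethod
    def from_file(cls, path, location: str = "") -> "TwoGroupYieldModel":
        return cls(ybio.read_measurements(path), location=location)

    @classmethod
    def from_simulation(cls, layouts, config: SimulationConfig,
                        location: str = "simulated") -> "TwoGroupYieldModel":
        return cls(simulate_measurements(layouts, config), location=location)

    # ---- preprocessing ------------------------------------------------
    def preprocess(self, filter_outliers: bool = True, filter_scope: str = "group",
                   balance: bool = True, target_per_group: int | None = None,
                   seed: int = 0) -> "TwoGroupYieldModel":
        """Return a new model with the 3-sigma filter and/or stratified
        balancing applied; the filter report and sampling plan ride along."""
        df = self.data
        reports = None
        plan = None
        if filter_outliers:
            df, reports = three_sigma_filter(df, scope=filter_scope)
        if balance:
            df, plan = stratified_balance_sample(
                df, target_per_group=target_per_group, seed=seed)
        out = TwoGroupYieldModel(df, location=self.location)
        out.filter_reports = reports
        out.sampling_plan = plan
        return out

    def group_yields(self, group: str) -> np.ndarray:
        return self.data.loc[self.data["group"] == group,
                             "dry_yield_kg_ha"].to_numpy()

    # ---- estimation ---------------------------------------------------
    def fit(self, prior_scale_factor: float = 10.0,
            sampler_config: SamplerConfig | None = None,
            contrast_mode: str = "predictive", hdi_mass: float = 0.95,
            rhat_threshold: float = 1.01, seed: int = 0) -> "TwoGroupYieldResults":
        """Sample both group posteriors and compute the contrast.

        ``seed`` controls every stochastic step (chain starts, proposals, the
        predictive draws); two fits of the same model with the same arguments
        are bit-identical.
        """
        base = sampler_config if sampler_config is not None else SamplerConfig()
        seeds = np.random.SeedSequence(seed).generate_state(3) & 0x7FFFFFFF
        posteriors = {}
        for g, s in zip((TEST, CONTROL), seeds):
            cfg = SamplerConfig(**{**base.__dict__, "seed": int(s)})
            posteriors[g] = fit_group(self.group_yields(g),
                                      prior_scale_factor=prior_scale_factor,
                                      config=cfg, rhat_threshold=rhat_threshold)
        result = compute_contrast(posteriors[TEST], posteriors[CONTROL],
                                  mode=contrast_mode, hdi_mass=hdi_mass,
                                  seed=int(seeds[2]))
        return TwoGroupYieldResults(model=self, test_posterior=posteriors[TEST],
                                    control_posterior=posteriors[CONTROL],
                                    contrast_result=result, seed=seed)


@dataclass
class TwoGroupYieldResults:
    """Fitted posteriors and effect summaries for one location."""

    model: TwoGroupYieldModel
    test_posterior: GroupPosterior
    control_posterior: GroupPosterior
    contrast_result: ContrastResult
    seed: int = 0

    # posterior point summaries (kg/ha)
    @property
    def mu_test(self) -> float:
        return float(self.test_posterior.mu_flat.mean())

    @property
    def mu_control(self) -> float:
        return float(self.control_posterior.mu_flat.mean())

    @property
    def sigma_test(self) -> float:
        return float(self.test_posterior.sigma_flat.mean())

    @property
    def sigma_control(self) -> float:
        return float(self.control_posterior.sigma_flat.mean())

    @property
    def contrast_mean(self) -> float:
        return self.contrast_result.contrast_mean

    @property
    def hdi(self) -> tuple[float, float]:
        return (self.contrast_result.hdi_low, self.contrast_result.hdi_high)

    @property
    def superiority_percent(self) -> float:
        return 100.0 * self.contrast_result.superiority_prob

    @property
    def gain_percent(self) -> int:
        from .report import compute_gain
        return compute_gain(self.mu_test, self.mu_control)

    def summary(self) -> str:
        """Plain-text summary table (yields in kg/ha)."""
        c = self.contrast_result
        lines = [
            "Bayesian two-group yield comparison"
            + (f" — {self.model.location}" if self.model.location else ""),
            "=" * 58,
            f"{'group':<10}{'n':>7}{'post. mean mu':>16}{'post. mean sigma':>18}",
            "-" * 58,
        ]
        for label, post in (("test", self.test_posterior),
                            ("control", self.control_posterior)):
            lines.append(f"{label:<10}{post.n_obs:>7d}"
                         f"{post.mu_flat.mean():>16.1f}"
                         f"{post.sigma_flat.mean():>18.1f}")
        lines += [
            "-" * 58,
            f"contrast mean ({c.mode}): {c.contrast_mean:.1f} kg/ha",
            f"{100 * c.hdi_mass:.0f}% HDI: [{c.hdi_low:.1f}, {c.hdi_high:.1f}] kg/ha",
            f"P(test > control): {c.superiority_prob:.3f}",
            f"gain: {self.gain_percent}%",
            "-" * 58,
            "diagnostics: "
            + ", ".join(f"{g} rhat(mu)={p.rhat['mu']:.4f} ess(mu)={p.ess['mu']:.0f}"
                        for g, p in (("test", self.test_posterior),
                                     ("control", self.control_posterior))),
        ]
        return "\n".join(lines)

    def plot(self, figsize=(12, 3.5)):
        from .plotting import plot_contrast_panels
        return plot_contrast_panels(self, figsize=figsize)
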