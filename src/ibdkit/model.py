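"""Maximum-likelihood split-time inference from a binned IBD spectrum.

:class:`SplitTimeModel` wraps an observed :class:`~ibdkit.split_model.BinnedSpectrum`
together with the fixed quantities of the two-island split model (genetic map,
sampling offset) and exposes ``fit()`` over a dense 2D (T0, N0) grid, in the
spirit of statsmodels model/results pairs. :class:`SplitTimeResults` carries
the estimates, the log-likelihood surface, the joint 95% confidence region
(log-likelihood within 1.92 of the maximum, i.e. half the chi-square 95%
quantile with 1 df) and its per-parameter projections, plus diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .split_model import (
    DEFAULT_BIN_EDGES_CM,
    BinnedSpectrum,
    ModelPrediction,
    SplitModelParams,
    chi2_half_threshold,
    compute_mu_grid,
    expected_bin_counts,
    poisson_loglik,
)

__all__ = ["SplitTimeModel", "SplitTimeResults", "grid_fit", "default_grids"]


def default_grids(delta_gens: float) -> tuple[np.ndarray, np.ndarray]:
    """Default search grids: T0 in {delta, ..., delta+150} step 1 (the split
    cannot predate the older sample's side of the offset), N0 log-spaced with
    201 points over [1e2, 1e6]."""
    t0 = np.arange(delta_gens, delta_gens + 151.0)
    n0 = np.logspace(2.0, 6.0, 201)
    return t0, n0


class SplitTimeModel:
    """Two-island split model for an observed between-group IBD spectrum.

    Parameters
    ----------
    spectrum : BinnedSpectrum
        Observed segment counts per length bin and the number of inter-group
        diploid pairs.
    delta_gens : float
        Sampling offset between the groups in generations (>= 0).
    gmap : GenomeMap, optional
        Genetic map; defaults to the bundled 22-autosome map.
    """

    def __init__(
        self,
        spectrum: BinnedSpectrum,
        delta_gens: float,
        gmap: GenomeMap | None = None,
    ) -> None:
        if delta_gens < 0:
            raise ValueError("delta_gens must be >= 0")
        self.spectrum = spectrum
        self.delta_gens = float(delta_gens)
        self.gmap = gmap if gmap is not None else GenomeMap.default()

    @classmethod
    def from_segments(
        cls,
        segments: pd.DataFrame,
        n_pairs: int,
        delta_gens: float,
        bin_edges_cM=DEFAULT_BIN_EDGES_CM,
        gmap: GenomeMap | None = None,
    ) -> "SplitTimeModel":
        """Build the model directly from a filtered between-group segment table."""
        spectrum = BinnedSpectrum.from_segments(segments, n_pairs, bin_edges_cM)
        return cls(spectrum, delta_gens, gmap)

    def params(self, n0: float, t0: float) -> SplitModelParams:
        return SplitModelParams(
            n0=n0, t0=t0, delta_gens=self.delta_gens, gmap=self.gmap
        )

    def predict(self, n0: float, t0: float) -> ModelPrediction:
        """Expected counts per bin at the given parameters."""
        return expected_bin_counts(
            self.params(n0, t0), self.spectrum.bin_edges_cM, self.spectrum.n_pairs
        )

    def loglike(self, n0: float, t0: float) -> float:
        """Composite Poisson log-likelihood at the given parameters."""
        return poisson_loglik(self.spectrum, self.predict(n0, t0))

    def mu_grid(self, t0_grid, n0_grid) -> np.ndarray:
        """Expected-count grid, shape (nT0, nN0, n_bins); reusable across
        spectra sharing bins, pair count, offset and map."""
        return compute_mu_grid(
            self.gmap,
            self.delta_gens,
            np.asarray(t0_grid, dtype=float),
            np.asarray(n0_grid, dtype=float),
            self.spectrum.bin_edges_cM,
            self.spectrum.n_pairs,
        )

    def fit(
        self,
        t0_grid=None,
        n0_grid=None,
        confidence: float = 0.95,
        mu_grid: np.ndarray | None = None,
    ) -> "SplitTimeResults":
        """Maximize the composite likelihood over a dense (T0, N0) grid.

        Ties at the maximum are broken toward smaller T0 then smaller N0.
        The confidence region is the set of grid points whose log-likelihood
        is within half the chi-square(1) quantile of the maximum; per-parameter
        intervals are min/max projections of that region. A warning is issued
        when the region touches the grid boundary.

        ``mu_grid`` may carry a precomputed :meth:`mu_grid` result.
        """
        if t0_grid is None or n0_grid is None:
            d_t0, d_n0 = default_grids(self.delta_gens)
            t0_grid = d_t0 if t0_grid is None else np.asarray(t0_grid, dtype=float)
            n0_grid = d_n0 if n0_grid is None else np.asarray(n0_grid, dtype=float)
        else:
            t0_grid = np.asarray(t0_grid, dtype=float)
            n0_grid = np.asarray(n0_grid, dtype=float)
        if t0_grid.size == 0 or n0_grid.size == 0:
            raise ValueError("grids must be non-empty")
        if mu_grid is None:
            mu_grid = self.mu_grid(t0_grid, n0_grid)
        expected_shape = (len(t0_grid), len(n0_grid), self.spectrum.n_bins)
        if mu_grid.shape != expected_shape:
            raise ValueError(
                f"mu_grid shape {mu_grid.shape} != expected {expected_shape}"
            )

        obs = np.asarray(self.spectrum.observed, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_mu = np.where(mu_grid > 0, np.log(mu_grid), -np.inf)
        ll = (np.where(obs > 0, log_mu * obs, 0.0) - mu_grid).sum(axis=2)
        ll[np.any((mu_grid <= 0) & (obs > 0), axis=2)] = -np.inf

        if not np.any(np.isfinite(ll)):
            raise RuntimeError("fit failure: log-likelihood is -inf on the whole grid")

        # argmax with ties broken toward smaller T0, then smaller N0
        best_flat = int(np.argmax(np.where(np.isfinite(ll), ll, -np.inf)))
        i_best, j_best = np.unravel_index(best_flat, ll.shape)
        ll_max = ll[i_best, j_best]
        tied = np.argwhere(ll == ll_max)
        i_best, j_best = tied[np.lexsort((tied[:, 1], tied[:, 0]))][0]

        drop = chi2_half_threshold(confidence, df=1)
        region = ll >= ll_max - drop

        t_in = t0_grid[np.any(region, axis=1)]
        n_in = n0_grid[np.any(region, axis=0)]
        ci_t0 = (float(t_in.min()), float(t_in.max()))
        ci_n0 = (float(n_in.min()), float(n_in.max()))

        # touching T0 = delta is the model's hard constraint (the split cannot
        # postdate the older sample), not a grid truncation: no warning there
        lower_t0_is_constraint = np.isclose(t0_grid[0], self.delta_gens)
        boundary = bool(
            (region[0, :].any() and not lower_t0_is_constraint)
            or region[-1, :].any()
            or region[:, 0].any()
            or region[:, -1].any()
        )
        if boundary:
            warnings.warn(
                "confidence region touches the grid boundary; widen the grid",
                RuntimeWarning,
                stacklevel=2,
            )

        return SplitTimeResults(
            model=self,
            n0_hat=float(n0_grid[j_best]),
            t0_hat=float(t0_grid[i_best]),
            llf=float(ll_max),
            t0_grid=t0_grid,
            n0_grid=n0_grid,
            loglik_surface=ll,
            region95=region,
            ci_t0=ci_t0,
            ci_n0=ci_n0,
            confidence=confidence,
            loglik_drop=drop,
            region_touches_boundary=boundary,
        )


@dataclass
class SplitTimeResults:
    """Grid-search ML fit of the two-island split model."""

    model: SplitTimeModel
    n0_hat: float
    t0_hat: float
    llf: float
    t0_grid: np.ndarray
    n0_grid: np.ndarray
    loglik_surface: np.ndarray
    region95: np.ndarray
    ci_t0: tuple[float, float]
    ci_n0: tuple[float, float]
    confidence: float
    loglik_drop: float
    region_touches_boundary: bool
    _prediction: ModelPrediction | None = field(default=None, repr=False)

    @property
    def params(self) -> dict[str, float]:
        return {"N0": self.n0_hat, "T0": self.t0_hat}

    @property
    def prediction(self) -> ModelPrediction:
        """Expected counts at the ML estimates."""
        if self._prediction is None:
            self._prediction = self.model.predict(self.n0_hat, self.t0_hat)
        return self._prediction

    def predict_vs_observed(self) -> pd.DataFrame:
        """Per-bin diagnostic table with Pearson residuals (O - mu)/sqrt(mu)."""
        edges = self.model.spectrum.bin_edges_cM
        obs = np.asarray(self.model.spectrum.observed, dtype=float)
        mu = np.asarray(self.prediction.mu, dtype=float)
        labels = [
            f"[{lo:g}, {hi:g})" if np.isfinite(hi) else f">={lo:g}"
            for lo, hi in zip(edges[:-1], edges[1:])
        ]
        return pd.DataFrame(
            {
                "bin_cM": labels,
                "observed": obs.astype(int),
                "expected": mu,
                "pearson_resid": (obs - mu) / np.sqrt(mu),
            }
        )

    @property
    def resid_pearson(self) -> np.ndarray:
        return self.predict_vs_observed()["pearson_resid"].to_numpy()

    def surface_frame(self) -> pd.DataFrame:
        """Long-format log-likelihood surface (n0, t0, loglik, in_region95)."""
        tt, nn = np.meshgrid(self.t0_grid, self.n0_grid, indexing="ij")
        return pd.DataFrame(
            {
                "t0": tt.ravel(),
                "n0": nn.ravel(),
                "loglik": self.loglik_surface.ravel(),
                "in_region95": self.region95.ravel(),
            }
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        s = self.model.spectrum
        pct = 100.0 * self.confidence
        lines = [
            "Two-island split model: grid maximum likelihood",
            "=" * 55,
            f"Bins (cM):        {s.bin_edges_cM}",
            f"Observed counts:  {s.observed}  (n_pairs={s.n_pairs})",
            f"Sampling offset:  {self.model.delta_gens:g} generations",
            "-" * 55,
            f"T0 (split time):  {self.t0_hat:g} generations "
            f"({pct:g}% CI: {self.ci_t0[0]:g} to {self.ci_t0[1]:g})",
            f"N0 (ancestral):   {self.n0_hat:,.0f} diploids "
            f"({pct:g}% CI: {self.ci_n0[0]:,.0f} to {self.ci_n0[1]:,.0f})",
            f"log-likelihood:   {self.llf:.4f}  (region drop {self.loglik_drop:.4g})",
        ]
        if self.region_touches_boundary:
            lines.append("WARNING: confidence region touches the grid boundary")
        lines.append("-" * 55)
        lines.append(self.predict_vs_observed().to_string(index=False))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimates": {"N0": self.n0_hat, "T0": self.t0_hat},
            "confidence": self.confidence,
            "loglik_drop": self.loglik_drop,
            "ci_T0": list(self.ci_t0),
            "ci_N0": list(self.ci_n0),
            "llf": self.llf,
            "delta_gens": self.model.delta_gens,
            "n_pairs": self.model.spectrum.n_pairs,
            "bin_edges_cM": list(self.model.spectrum.bin_edges_cM),
            "observed": list(self.model.spectrum.observed),
            "expected": list(self.prediction.mu),
            "region_touches_boundary": self.region_touches_boundary,
            "grid": {
                "t0": [float(self.t0_grid.min()), float(self.t0_grid.max()),
                       int(len(self.t0_grid))],
                "n0": [float(self.n0_grid.min()), float(self.n0_grid.max()),
                       int(len(self.n0_grid))],
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def export_surface(self, path: str | Path) -> None:
        self.surface_frame().to_csv(path, sep="\t", index=False)

    def plot_surface(self, ax=None):
        """Contour of the log-likelihood surface with the confidence region."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ll = self.loglik_surface
        finite = np.isfinite(ll)
        floor = ll[finite].max() - 20.0
        ax.contourf(
            self.t0_grid, self.n0_grid, np.maximum(ll, floor).T, levels=30,
            cmap="viridis",
        )
        ax.contour(
            self.t0_grid, self.n0_grid, ll.T,
            levels=[self.llf - self.loglik_drop], colors="white",
        )
        ax.plot([self.t0_hat], [self.n0_hat], "r+", markersize=12)
        ax.set_yscale("log")
        ax.set_xlabel("split time T0 (generations)")
        ax.set_ylabel("ancestral size N0 (diploids)")
        return ax


def grid_fit(
    spectrum: BinnedSpectrum,
    delta_gens: float,
    t0_grid=None,
    n0_grid=None,
    gmap: GenomeMap | None = None,
    confidence: float = 0.95,
    mu_grid: np.ndarray | None = None,
) -> SplitTimeResults:
    """Functional wrapper: build a :class:`SplitTimeModel` and fit it."""
    return SplitTimeModel(spectrum, delta_gens, gmap).fit(
        t0_grid=t0_grid, n0_grid=n0_grid, confidence=confidence, mu_grid=mu_grid
    )
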