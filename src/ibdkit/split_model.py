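"""Expected IBD segment-length spectra under a two-island split model.

Two populations descend from a single ancestral population of diploid
effective size ``N0`` and exchange no migrants after splitting ``T0``
generations before the younger sample. The samples may be heterochronous:
the older group antedates the younger by ``delta`` generations, so two
lineages sampled one from each group have met ``m(t) = 2t - delta`` meioses
when their common ancestor lived ``t`` generations before the younger
sample. Coalescence between groups is only possible in the ancestral
population, i.e. for ``t >= t_min = max(T0, delta)``, and happens at rate
``1/(2 N0)`` per generation.

Given a total meiosis count ``m``, the expected density of IBD segments of
length ``l`` (Morgans) per haplotype pair is the classical crossover-survival
result summed over chromosomes of map length ``L_c``::

    phi(l | m) = sum_{c: L_c > l} [ (L_c - l) m^2 + 2 m ] exp(-m l)

Averaging over the coalescence time gives the marginal density

    lambda(l) = int_{t_min}^inf  (1/(2 N0)) exp(-(t - t_min)/(2 N0))
                                 * phi(l | 2t - delta)  dt

Because ``m`` is linear in ``t``, the integral reduces in closed form to
moments of an exponential: with ``beta = 1/(2 N0)``, ``m0 = 2 t_min - delta``
and ``a = beta + 2 l``,

    lambda_c(l) = beta exp(-m0 l) [ (L_c - l)(8/a^3 + 4 m0/a^2 + m0^2/a)
                                    + 4/a^2 + 2 m0/a ]

Binned expected counts follow as ``mu_b = 4 n_pairs int_bin lambda`` (four
haplotype pairs per diploid pair), and the composite log-likelihood of an
observed spectrum treats bins as independent Poisson counts.

Public interfaces are in cM and generations; lengths are converted to
Morgans internally and only here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .genome import GenomeMap

__all__ = [
    "SplitModelParams",
    "BinnedSpectrum",
    "ModelPrediction",
    "segment_density",
    "expected_density_split",
    "total_rate",
    "expected_bin_counts",
    "poisson_loglik",
    "chi2_half_threshold",
    "time_offset_generations",
    "compute_mu_grid",
    "DEFAULT_BIN_EDGES_CM",
]

#: default length bins (cM); the last bin is open-ended
DEFAULT_BIN_EDGES_CM = (8.0, 12.0, 16.0, 20.0, np.inf)

NEG_INF = float("-inf")


@dataclass(frozen=True)
class SplitModelParams:
    """Parameters of the two-island split model.

    Attributes
    ----------
    n0 : float
        Ancestral diploid effective size; pairwise coalescence rate 1/(2 n0).
    t0 : float
        Split time in generations before the *younger* sample.
    delta_gens : float
        Sampling-time offset between the two groups, generations (>= 0).
    gmap : GenomeMap
        Genetic map supplying per-chromosome lengths.
    """

    n0: float
    t0: float
    delta_gens: float
    gmap: GenomeMap = field(default_factory=GenomeMap.default)

    def __post_init__(self) -> None:
        if not self.n0 > 0:
            raise ValueError("n0 must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if self.delta_gens < 0:
            raise ValueError("delta_gens must be >= 0")

    @property
    def t_min(self) -> float:
        """Earliest possible between-group coalescence time (generations)."""
        return max(self.t0, self.delta_gens)

    @property
    def m0(self) -> float:
        """Meiosis count at the earliest coalescence time."""
        return 2.0 * self.t_min - self.delta_gens


@dataclass(frozen=True)
class BinnedSpectrum:
    """Observed IBD segment counts per length bin for one group pair."""

    bin_edges_cM: tuple[float, ...]
    observed: tuple[int, ...]
    n_pairs: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_cM, dtype=float)
        obs = np.asarray(self.observed)
        if edges.ndim != 1 or len(edges) < 2:
            raise ValueError("need at least two bin edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(obs) != len(edges) - 1:
            raise ValueError("observed must have one entry per bin")
        if np.any(obs < 0) or np.any(obs != np.floor(obs)):
            raise ValueError("observed counts must be nonnegative integers")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        object.__setattr__(self, "bin_edges_cM", tuple(float(e) for e in edges))
        object.__setattr__(self, "observed", tuple(int(o) for o in obs))

    @property
    def n_bins(self) -> int:
        return len(self.observed)

    @classmethod
    def from_segments(
        cls,
        segments,
        n_pairs: int,
        bin_edges_cM=DEFAULT_BIN_EDGES_CM,
    ) -> "BinnedSpectrum":
        """Bin a segment table's lengths (cM) into an observed spectrum."""
        edges = np.asarray(bin_edges_cM, dtype=float)
        lengths = np.asarray(segments["length_cM"], dtype=float)
        counts, _ = np.histogram(lengths, bins=edges)
        return cls(tuple(edges), tuple(int(c) for c in counts), n_pairs)


@dataclass(frozen=True)
class ModelPrediction:
    """Expected counts per bin under fixed parameters."""

    bin_edges_cM: tuple[float, ...]
    mu: tuple[float, ...]
    n_pairs: int

    @property
    def n_bins(self) -> int:
        return len(self.mu)


def segment_density(l, m: float, gmap: GenomeMap) -> np.ndarray | float:
    """Expected IBD-segment length density phi(l | m) per haplotype pair.

    ``l`` is in Morgans (scalar or array), ``m`` the total meiosis count.
    Chromosomes shorter than ``l`` contribute nothing.
    """
    l_arr = np.asarray(l, dtype=float)
    if np.any(l_arr <= 0):
        raise ValueError("segment length l must be > 0 (Morgans)")
    if not m > 0:
        raise ValueError("meiosis count m must be > 0")
    L = gmap.lengths_morgan  # (C,)
    ll = l_arr[..., None]  # (..., C)
    per_chrom = np.where(L > ll, ((L - ll) * m * m + 2.0 * m) * np.exp(-m * ll), 0.0)
    out = per_chrom.sum(axis=-1)
    return out if out.ndim else float(out)


def _density_closed_form_per_chrom(
    l_morgan: np.ndarray, params: SplitModelParams
) -> np.ndarray:
    """Per-chromosome closed-form lambda_c(l), shape (..., n_chrom)."""
    l = np.asarray(l_morgan, dtype=float)
    beta = 1.0 / (2.0 * params.n0)
    m0 = params.m0
    L = params.gmap.lengths_morgan
    ll = l[..., None]
    a = beta + 2.0 * ll
    quad_term = 8.0 / a**3 + 4.0 * m0 / a**2 + m0**2 / a
    lin_term = 4.0 / a**2 + 2.0 * m0 / a
    return np.where(
        L > ll,
        beta * np.exp(-m0 * ll) * ((L - ll) * quad_term + lin_term),
        0.0,
    )


def _density_closed_form(l_morgan: np.ndarray, params: SplitModelParams) -> np.ndarray:
    """Closed-form lambda(l): exponential moments of the linear-in-t meiosis count."""
    return _density_closed_form_per_chrom(l_morgan, params).sum(axis=-1)


def _density_quadrature(l_morgan: np.ndarray, params: SplitModelParams) -> np.ndarray:
    """Adaptive-quadrature lambda(l); cross-check for the closed form."""
    beta = 1.0 / (2.0 * params.n0)
    t_min = params.t_min
    delta = params.delta_gens

    def one(l: float) -> float:
        def integrand(t: float) -> float:
            m = 2.0 * t - delta
            return beta * math.exp(-beta * (t - t_min)) * float(
                segment_density(l, m, params.gmap)
            )

        val, err = integrate.quad(
            integrand, t_min, np.inf, epsabs=0.0, epsrel=1e-12, limit=400
        )
        if not np.isfinite(val):
            raise FloatingPointError(
                f"quadrature failed at l={l}: value={val}, abserr={err}"
            )
        return val

    l = np.asarray(l_morgan, dtype=float)
    out = np.asarray([one(x) for x in np.atleast_1d(l)])
    return out.reshape(l.shape)


def expected_density_split(
    l_cM, params: SplitModelParams, method: str = "closed_form"
) -> np.ndarray | float:
    """Marginal IBD length density lambda per haplotype pair, at lengths in cM.

    Returned density is per Morgan. ``method`` is ``"closed_form"`` (default,
    exact) or ``"quadrature"`` (adaptive integration over coalescence time);
    the two agree to ~1e-12 relative and the equivalence is enforced in the
    test suite.
    """
    l_morgan = np.asarray(l_cM, dtype=float) / 100.0
    if np.any(l_morgan <= 0):
        raise ValueError("lengths must be > 0")
    if method == "closed_form":
        out = _density_closed_form(l_morgan, params)
    elif method == "quadrature":
        out = _density_quadrature(l_morgan, params)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out if np.ndim(out) else float(out)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _piecewise_nodes(
    lo: float, hi: float, lengths_morgan: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on [lo, hi], split at every chromosome
    length inside the interval: lambda(l) is smooth between, but kinked at,
    the points where a chromosome stops hosting segments."""
    cuts = np.unique(lengths_morgan[(lengths_morgan > lo) & (lengths_morgan < hi)])
    edges = np.concatenate([[lo], cuts, [hi]])
    nodes, weights = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        nodes.append(mid + half * _GL_NODES)
        weights.append(half * _GL_WEIGHTS)
    return np.concatenate(nodes), np.concatenate(weights)


def _bin_integral_morgan(
    lo: float, hi: float, params: SplitModelParams
) -> float:
    """integral of lambda over [lo, hi] (Morgans), piecewise Gauss-Legendre."""
    L = params.gmap.lengths_morgan
    hi = min(hi, float(L.max()))
    if hi <= lo:
        return 0.0
    x, w = _piecewise_nodes(lo, hi, L)
    return float(np.dot(w, _density_closed_form(x, params)))


def total_rate(params: SplitModelParams, min_len_cM: float = 8.0) -> float:
    """Lambda = integral of lambda(l) above the emission floor, per haplotype pair."""
    lo = min_len_cM / 100.0
    hi = params.gmap.lengths_morgan.max()
    if lo >= hi:
        return 0.0
    rate = _bin_integral_morgan(lo, hi, params)
    if not np.isfinite(rate):
        raise FloatingPointError("non-finite total segment rate")
    return rate


def expected_bin_counts(
    params: SplitModelParams,
    bin_edges_cM=DEFAULT_BIN_EDGES_CM,
    n_pairs: int = 1,
) -> ModelPrediction:
    """Expected counts mu_b = 4 n_pairs * int_bin lambda(l) dl per length bin."""
    edges = np.asarray(bin_edges_cM, dtype=float) / 100.0
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    mu = [
        4.0 * n_pairs * _bin_integral_morgan(lo, hi, params)
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return ModelPrediction(
        bin_edges_cM=tuple(float(e) * 100.0 for e in edges),
        mu=tuple(mu),
        n_pairs=n_pairs,
    )


def poisson_loglik(spectrum: BinnedSpectrum, prediction: ModelPrediction) -> float:
    """Composite Poisson log-likelihood sum_b O_b ln(mu_b) - mu_b.

    The additive log(O_b!) constant is dropped. Bins with mu_b <= 0 and a
    positive observed count yield ``-inf``.
    """
    if spectrum.n_bins != prediction.n_bins:
        raise ValueError("spectrum and prediction binnings differ")
    obs = np.asarray(spectrum.observed, dtype=float)
    mu = np.asarray(prediction.mu, dtype=float)
    if np.any((mu <= 0) & (obs > 0)):
        return NEG_INF
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(mu), 0.0) - mu
    return float(terms.sum())


def chi2_half_threshold(confidence: float = 0.95, df: int = 1) -> float:
    """Half the chi-square quantile: the log-likelihood drop bounding the
    confidence region (1.92 for 95%, 1 df)."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    return float(stats.chi2.ppf(confidence, df) / 2.0)


def time_offset_generations(
    date1_CE: float, date2_CE: float, gen_years: float = 29.0
) -> int:
    """Sampling offset in generations between two median dates.

    Rounds ``|date1 - date2| / gen_years`` half away from zero.
    """
    if not gen_years > 0:
        raise ValueError("gen_years must be > 0")
    x = abs(date1_CE - date2_CE) / gen_years
    return int(math.floor(x + 0.5))


def compute_mu_grid(
    gmap: GenomeMap,
    delta_gens: float,
    t0_grid: np.ndarray,
    n0_grid: np.ndarray,
    bin_edges_cM=DEFAULT_BIN_EDGES_CM,
    n_pairs: int = 1,
) -> np.ndarray:
    """Expected bin counts on a full (T0, N0) grid, shape (nT0, nN0, n_bins).

    The log-likelihood surface for any observed spectrum with the same
    binning, pair count, offset and map is an affine function of this grid,
    so it can be computed once and reused across spectra (e.g. replicate
    fits). Vectorized over N0 and the quadrature nodes at fixed T0.
    """
    t0_grid = np.asarray(t0_grid, dtype=float)
    n0_grid = np.asarray(n0_grid, dtype=float)
    edges = np.asarray(bin_edges_cM, dtype=float) / 100.0
    L = gmap.lengths_morgan
    l_max = L.max()
    n_bins = len(edges) - 1

    # piecewise Gauss-Legendre nodes per bin, truncating the open bin at
    # l_max; a bin entirely beyond the longest chromosome has mu = 0
    nodes, weights, bin_ix = [], [], []
    for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        hi = min(hi, l_max)
        if hi <= lo:
            continue
        x, w_b = _piecewise_nodes(lo, hi, L)
        nodes.append(x)
        weights.append(w_b)
        bin_ix.append(np.full(x.shape, b))
    if not nodes:
        return np.zeros((len(t0_grid), len(n0_grid), n_bins))
    l = np.concatenate(nodes)  # (K,)
    w = np.concatenate(weights)
    bix = np.concatenate(bin_ix)

    beta = 1.0 / (2.0 * n0_grid)  # (nN0,)
    a = beta[:, None] + 2.0 * l[None, :]  # (nN0, K)
    inv_a = 1.0 / a
    host = L[None, :] > l[:, None]  # (K, C)
    sum_L = np.where(host, L[None, :] - l[:, None], 0.0).sum(axis=1)  # (K,)
    n_host = host.sum(axis=1).astype(float)  # (K,)

    mu = np.empty((len(t0_grid), len(n0_grid), n_bins))
    for i, t0 in enumerate(t0_grid):
        t_min = max(t0, delta_gens)
        m0 = 2.0 * t_min - delta_gens
        quad_term = 8.0 * inv_a**3 + 4.0 * m0 * inv_a**2 + m0**2 * inv_a
        lin_term = 4.0 * inv_a**2 + 2.0 * m0 * inv_a
        lam = (
            beta[:, None]
            * np.exp(-m0 * l)[None, :]
            * (sum_L[None, :] * quad_term + n_host[None, :] * lin_term)
        )  # (nN0, K)
        contrib = 4.0 * n_pairs * lam * w[None, :]
        for b in range(n_bins):
            mu[i, :, b] = contrib[:, bix == b].sum(axis=1)
    return mu
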