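"""Synthetic IBD segment tables.

Two generators provide data with the statistical structure the downstream
analyses assume:

* :func:`simulate_split_ibd` draws between-group segments from the same
  inhomogeneous Poisson process the split-model likelihood evaluates
  (coalescence time integrated out), so simulator and likelihood are matched
  by construction. A per-pair coalescence-time variant is available for
  overdispersion experiments.
* :func:`simulate_pedigree_ibd` gene-drops uniquely labelled founder
  haplotypes through small pedigrees (parent-offspring, full siblings,
  lineal and half-collateral chains of 1-8 meioses) with crossovers placed
  as a Poisson process of rate 1 per Morgan and no interference, and emits
  the realized IBD tracts between the two focal individuals.

:func:`build_reference_cloud` stacks pedigree replicates into the
(total cM, segment count) reference distribution used for degree-of-
relatedness classification.

Synthetic SNP counts are filled at 250 per cM so tables pass the default
density filter; default sample sizes (36 x 17 diploids) mirror the group
sizes of the fitted study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .io import SEGMENT_COLUMNS
from .split_model import (
    SplitModelParams,
    _density_closed_form_per_chrom,
    segment_density,
    total_rate,
)

__all__ = [
    "SimConfig",
    "PedigreeSpec",
    "RELATIONSHIPS",
    "simulate_split_ibd",
    "simulate_pedigree_ibd",
    "build_reference_cloud",
    "SNPS_PER_CM",
]

#: synthetic SNP density (per cM); comfortably above the 220/cM filter
SNPS_PER_CM = 250.0

RELATIONSHIPS = ("parent_child", "sibling", "lineal_chain", "half_collateral_chain")


@dataclass(frozen=True)
class SimConfig:
    """Sampling design for the split-model simulator.

    Defaults mirror the study design the model is fitted under: 36 diploids
    in the older group, 17 in the younger, 8 cM emission floor.
    """

    seed: int
    n1: int = 36
    n2: int = 17
    min_len_cM: float = 8.0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("sample sizes must be >= 1")
        if not self.min_len_cM > 0:
            raise ValueError("min_len_cM must be > 0")


@dataclass(frozen=True)
class PedigreeSpec:
    """A pedigree relationship between two focal diploid individuals.

    ``degree`` is the number of meioses on the connecting path through a
    single common ancestor; full siblings are degree 1 with two common
    ancestors. Chains must have degree >= 2; parent-child and siblings are
    the two degree-1 relationships.
    """

    degree: int
    relationship: str
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.relationship not in RELATIONSHIPS:
            raise ValueError(f"relationship must be one of {RELATIONSHIPS}")
        if not 1 <= self.degree <= 8:
            raise ValueError("degree must be in 1..8")
        if self.relationship in ("parent_child", "sibling") and self.degree != 1:
            raise ValueError(f"{self.relationship} is a degree-1 relationship")
        if self.relationship.endswith("chain") and self.degree < 2:
            raise ValueError("chains require degree >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# split-model simulator


def _length_sampler(params: SplitModelParams, min_len_cM: float, n_grid: int = 4096):
    """Inverse-CDF sampler for the normalized density lambda(l)/Lambda.

    Returns (sample_fn, per-chromosome density matrix on the grid).
    """
    lo = min_len_cM / 100.0
    hi = params.gmap.lengths_morgan.max()
    grid = np.linspace(lo, hi, n_grid)
    dens_pc = _density_closed_form_per_chrom(grid, params)  # (G, C)
    dens = dens_pc.sum(axis=1)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
    if cdf[-1] <= 0:
        raise ValueError("zero segment rate above the emission floor")
    cdf /= cdf[-1]

    def sample(rng: np.random.Generator, k: int) -> np.ndarray:
        return np.interp(rng.uniform(size=k), cdf, grid)

    return sample, grid, dens_pc


def _assign_chromosomes(
    rng: np.random.Generator,
    lengths_morgan: np.ndarray,
    params: SplitModelParams,
) -> np.ndarray:
    """Draw a hosting chromosome per segment, P(c | l) ~ lambda_c(l)."""
    dens_pc = _density_closed_form_per_chrom(lengths_morgan, params)  # (k, C)
    totals = dens_pc.sum(axis=1, keepdims=True)
    probs = dens_pc / np.where(totals > 0, totals, 1.0)
    cum = np.cumsum(probs, axis=1)
    u = rng.uniform(size=(len(lengths_morgan), 1))
    return (u < cum).argmax(axis=1)


def _emit_table(
    rng: np.random.Generator,
    lengths_morgan: np.ndarray,
    pair_idx: np.ndarray,
    ids1: list[str],
    ids2: list[str],
    params: SplitModelParams,
) -> pd.DataFrame:
    chrom_ix = _assign_chromosomes(rng, lengths_morgan, params)
    chroms = np.asarray(params.gmap.chroms)[chrom_ix]
    L = params.gmap.lengths_cm[chrom_ix]
    length_cm = lengths_morgan * 100.0
    start = rng.uniform(0.0, L - length_cm)
    n2 = len(ids2)
    frame = pd.DataFrame(
        {
            "iid1": [ids1[i // n2] for i in pair_idx],
            "iid2": [ids2[i % n2] for i in pair_idx],
            "chrom": chroms,
            "start_cM": start,
            "end_cM": start + length_cm,
            "length_cM": length_cm,
            "n_snps": np.round(length_cm * SNPS_PER_CM),
        }
    )
    order = np.lexsort(
        (frame["start_cM"], frame["chrom"], frame["iid2"], frame["iid1"])
    )
    return frame.iloc[order].reset_index(drop=True)[SEGMENT_COLUMNS]


def simulate_split_ibd(
    params: SplitModelParams,
    config: SimConfig,
    per_pair_times: bool = False,
) -> pd.DataFrame:
    """Simulate between-group IBD segments under the two-island split model.

    In the default (marginal) mode the total segment count over all
    ``n1 x n2`` diploid pairs is Poisson with mean ``4 n1 n2 Lambda`` where
    ``Lambda`` integrates the marginal length density above the emission
    floor; lengths are i.i.d. from the normalized density, each segment is
    assigned a hosting chromosome proportionally to that chromosome's
    density at its length, a uniform admissible start, and a uniformly
    chosen pair. With ``per_pair_times=True`` a coalescence time is drawn
    per diploid pair first, adding between-pair overdispersion.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ids1 = [f"A{i:03d}" for i in range(config.n1)]
    ids2 = [f"B{i:03d}" for i in range(config.n2)]
    n_pairs = config.n1 * config.n2

    if not per_pair_times:
        lam_total = total_rate(params, config.min_len_cM)
        if not np.isfinite(lam_total):
            raise ValueError("non-finite total segment rate")
        k = int(rng.poisson(4.0 * n_pairs * lam_total))
        sample, _, _ = _length_sampler(params, config.min_len_cM)
        lengths = sample(rng, k)
        pair_idx = rng.integers(0, n_pairs, size=k)
        return _emit_table(rng, lengths, pair_idx, ids1, ids2, params)

    # overdispersed variant: explicit coalescence time per diploid pair
    lo = config.min_len_cM / 100.0
    hi = params.gmap.lengths_morgan.max()
    grid = np.linspace(lo, hi, 4096)
    t = params.t_min + rng.exponential(2.0 * params.n0, size=n_pairs)
    all_lengths, all_pairs = [], []
    for i, ti in enumerate(t):
        m = 2.0 * ti - params.delta_gens
        dens = np.asarray(segment_density(grid, m, params.gmap))
        lam = np.trapezoid(dens, grid)
        k = int(rng.poisson(4.0 * lam))
        if k == 0:
            continue
        cdf = np.concatenate(
            [[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))]
        )
        cdf /= cdf[-1]
        all_lengths.append(np.interp(rng.uniform(size=k), cdf, grid))
        all_pairs.append(np.full(k, i))
    if not all_lengths:
        lengths = np.empty(0)
        pair_idx = np.empty(0, dtype=int)
    else:
        lengths = np.concatenate(all_lengths)
        pair_idx = np.concatenate(all_pairs)
    return _emit_table(rng, lengths, pair_idx, ids1, ids2, params)


# ---------------------------------------------------------------------------
# pedigree gene dropping

# A haplotype along one chromosome is a list of (start, end, founder-label)
# tuples covering [0, L) in Morgans.


def _founder_hap(length: float, label: int) -> list[tuple[float, float, int]]:
    return [(0.0, length, label)]


def _restrict(
    hap: list[tuple[float, float, int]], a: float, b: float
) -> list[tuple[float, float, int]]:
    out = []
    for s, e, lab in hap:
        if e <= a or s >= b:
            continue
        out.append((max(s, a), min(e, b), lab))
    return out


def _meiosis(
    rng: np.random.Generator,
    hap0: list[tuple[float, float, int]],
    hap1: list[tuple[float, float, int]],
    length: float,
) -> list[tuple[float, float, int]]:
    """One gamete: Poisson crossovers (rate 1/Morgan), uniform positions,
    random starting haplotype, no interference."""
    xs = np.sort(rng.uniform(0.0, length, rng.poisson(length)))
    cur = int(rng.integers(2))
    gamete: list[tuple[float, float, int]] = []
    prev = 0.0
    for x in list(xs) + [length]:
        if x > prev:
            gamete.extend(_restrict(hap0 if cur == 0 else hap1, prev, x))
        cur ^= 1
        prev = x
    return gamete


def _ibd_intervals(
    haps_a: list[list[tuple[float, float, int]]],
    haps_b: list[list[tuple[float, float, int]]],
) -> list[tuple[float, float]]:
    """Maximal intervals where any haplotype of A and any of B carry the
    same founder label (IBD >= 1 between the two diploids)."""
    tracks = haps_a + haps_b
    bps = sorted({p for hap in tracks for s, e, _ in hap for p in (s, e)})
    if len(bps) < 2:
        return []
    mids = [(lo + hi) / 2 for lo, hi in zip(bps[:-1], bps[1:])]
    ends = [np.asarray([e for _, e, _ in hap]) for hap in tracks]
    labs = [np.asarray([lab for _, _, lab in hap]) for hap in tracks]
    mids_arr = np.asarray(mids)
    lab_at = [
        lab[np.searchsorted(end, mids_arr, side="left")]
        for end, lab in zip(ends, labs)
    ]
    a1, a2 = lab_at[0], lab_at[1]
    b1, b2 = lab_at[2], lab_at[3]
    shared = (a1 == b1) | (a1 == b2) | (a2 == b1) | (a2 == b2)
    out: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(shared):
        if flag and start is None:
            start = bps[i]
        elif not flag and start is not None:
            out.append((start, bps[i]))
            start = None
    if start is not None:
        out.append((start, bps[-1]))
    return out


def _simulate_pair(
    rng: np.random.Generator, spec: PedigreeSpec, gmap: GenomeMap
) -> list[tuple[int, float, float]]:
    """One replicate: realized IBD intervals (chrom, start_M, end_M) between
    the two focal individuals."""
    intervals: list[tuple[int, float, float]] = []
    label = 0

    def fresh(length: float) -> list[tuple[float, float, int]]:
        nonlocal label
        label += 1
        return _founder_hap(length, label)

    for chrom, L_cm in zip(gmap.chroms, gmap.lengths_cm):
        L = L_cm / 100.0
        if spec.relationship == "parent_child":
            p = [fresh(L), fresh(L)]
            spouse = [fresh(L), fresh(L)]
            child = [_meiosis(rng, *p, L), _meiosis(rng, *spouse, L)]
            a, b = p, child
        elif spec.relationship == "sibling":
            p = [fresh(L), fresh(L)]
            m = [fresh(L), fresh(L)]
            a = [_meiosis(rng, *p, L), _meiosis(rng, *m, L)]
            b = [_meiosis(rng, *p, L), _meiosis(rng, *m, L)]
        elif spec.relationship == "lineal_chain":
            anc = [fresh(L), fresh(L)]
            gam = _meiosis(rng, *anc, L)
            for _ in range(spec.degree - 1):
                carrier = [gam, _meiosis(rng, *[fresh(L), fresh(L)], L)]
                gam = _meiosis(rng, *carrier, L)
            a, b = anc, [gam, _meiosis(rng, *[fresh(L), fresh(L)], L)]
        else:  # half_collateral_chain
            anc = [fresh(L), fresh(L)]
            d1 = spec.degree // 2
            d2 = spec.degree - d1

            def descend(n_meioses: int) -> list[tuple[float, float, int]]:
                g = _meiosis(rng, *anc, L)
                for _ in range(n_meioses - 1):
                    carrier = [g, _meiosis(rng, *[fresh(L), fresh(L)], L)]
                    g = _meiosis(rng, *carrier, L)
                return g

            a = [descend(d1), _meiosis(rng, *[fresh(L), fresh(L)], L)]
            b = [descend(d2), _meiosis(rng, *[fresh(L), fresh(L)], L)]
        for s, e in _ibd_intervals(a, b):
            intervals.append((chrom, s, e))
    return intervals


def _intervals_to_frame(
    intervals: list[tuple[int, float, float]],
    iid1: str,
    iid2: str,
    min_len_cM: float,
) -> pd.DataFrame:
    rows = []
    for chrom, s, e in intervals:
        length_cm = (e - s) * 100.0
        if length_cm < min_len_cM or length_cm <= 0:
            continue
        rows.append(
            (iid1, iid2, chrom, s * 100.0, e * 100.0, length_cm,
             round(length_cm * SNPS_PER_CM))
        )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def simulate_pedigree_ibd(
    spec: PedigreeSpec,
    gmap: GenomeMap | None = None,
    seed: int = 0,
    min_len_cM: float = 0.0,
) -> list[pd.DataFrame]:
    """Gene-drop ``spec.n_replicates`` pedigrees; one segment table each.

    Focal individuals are named ``ind1``/``ind2``. ``min_len_cM`` filters
    emitted tracts (0 keeps everything, e.g. for coverage checks; use 8.0
    to match the analysis floor).
    """
    gmap = gmap if gmap is not None else GenomeMap.default()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(spec.n_replicates):
        intervals = _simulate_pair(rng, spec, gmap)
        out.append(_intervals_to_frame(intervals, "ind1", "ind2", min_len_cM))
    return out


def _cloud_relationships(degree: int) -> list[str]:
    if degree == 1:
        return ["parent_child", "sibling"]
    return ["lineal_chain", "half_collateral_chain"]


def build_reference_cloud(
    degrees=range(1, 9),
    n_per_degree: int = 100,
    gmap: GenomeMap | None = None,
    min_len_cM: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference distribution of per-pair IBD summaries for degrees 1-8.

    Each degree contributes ``n_per_degree`` replicates split evenly over its
    two relationship variants (parent-child/sibling at degree 1, lineal and
    half-collateral chains beyond), summarised at the ``min_len_cM`` floor as
    (degree, relationship, sum_cM, n_segments, max_cM). Replicates sharing no
    tract at the floor appear with zeros; seed-reproducible.
    """
    gmap = gmap if gmap is not None else GenomeMap.default()
    rng = np.random.default_rng(seed)
    rows = []
    for degree in degrees:
        rels = _cloud_relationships(int(degree))
        n_first = n_per_degree // 2
        for rel, n_rep in zip(rels, (n_first, n_per_degree - n_first)):
            spec = PedigreeSpec(degree=int(degree), relationship=rel, n_replicates=1)
            for _ in range(n_rep):
                intervals = _simulate_pair(rng, spec, gmap)
                lens = np.asarray(
                    [
                        (e - s) * 100.0
                        for _, s, e in intervals
                        if (e - s) * 100.0 >= min_len_cM
                    ]
                )
                rows.append(
                    (
                        int(degree),
                        rel,
                        float(lens.sum()),
                        int(len(lens)),
                        float(lens.max()) if len(lens) else 0.0,
                    )
                )
    return pd.DataFrame(
        rows, columns=["degree", "relationship", "sum_cM", "n_segments", "max_cM"]
    )
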