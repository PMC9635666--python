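"""Population-genetic summary statistics on haplotype samples.

Nucleotide diversity, segregating sites, Hudson's FST (ratio of averages),
and pairwise linkage disequilibrium (D, D', r^2) — used for calibration
checks and as the input statistics for recombination-rate estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wf import SampleSet

__all__ = [
    "DiversitySummary",
    "diversity",
    "hudson_fst",
    "pairwise_ld",
    "site_pair_counts",
    "island_fst",
    "expected_split_fst",
]


@dataclass(frozen=True)
class DiversitySummary:
    pi_per_site: float
    segregating_sites: int
    n_hap: int
    fst: float | None = None
    fst_raw: float | None = None


def diversity(sample: SampleSet) -> DiversitySummary:
    """Nucleotide diversity per site and the number of segregating sites.

    pi/site = sum over sites of 2*p*(1-p)*n/(n-1), divided by the genome
    length L (monomorphic sites contribute zero, so dropping them from the
    sample is harmless).
    """
    n = sample.n_hap
    if n < 2:
        raise ValueError("diversity requires at least two haplotypes")
    if sample.n_sites == 0:
        return DiversitySummary(0.0, 0, n)
    p = sample.H.mean(axis=0)
    seg = (p > 0) & (p < 1)
    pi = float((2.0 * p * (1.0 - p) * n / (n - 1)).sum() / sample.L)
    return DiversitySummary(pi, int(seg.sum()), n)


def _align_positions(a: SampleSet, b: SampleSet) -> tuple[np.ndarray, np.ndarray]:
    """Allele frequencies of both samples on the union of their positions.

    A position absent from one sample is treated as monomorphic ancestral
    there; paired draws from the simulator share column sets, making this
    exact.
    """
    if a.n_sites == b.n_sites and np.array_equal(a.positions, b.positions):
        return a.H.mean(axis=0), b.H.mean(axis=0)
    union = np.union1d(a.positions, b.positions)
    out = []
    for s in (a, b):
        p = np.zeros(len(union))
        idx = np.searchsorted(union, s.positions)
        p[idx] = s.H.mean(axis=0)
        out.append(p)
    return out[0], out[1]


def hudson_fst(sample_p1: SampleSet, sample_p2: SampleSet) -> DiversitySummary:
    """Hudson's FST: 1 - pi_within / pi_between (ratio of sums over sites).

    pi_within averages the two sample-size-corrected within-population
    heterozygosities; pi_between is the mean pairwise difference between
    populations.  Undefined (None) when pi_between is zero; the raw value
    is retained alongside a [0, 1]-clamped one.
    """
    n1, n2 = sample_p1.n_hap, sample_p2.n_hap
    if n1 < 2 or n2 < 2:
        raise ValueError("hudson_fst requires >= 2 haplotypes per population")
    p1, p2 = _align_positions(sample_p1, sample_p2)
    within = 0.5 * (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1))
    between = p1 * (1 - p2) + p2 * (1 - p1)
    sw, sb = float(within.sum()), float(between.sum())
    L = sample_p1.L
    pi_w = 0.5 * (diversity(sample_p1).pi_per_site + diversity(sample_p2).pi_per_site)
    if sb == 0.0:
        return DiversitySummary(pi_w, int(len(p1)), n1 + n2, fst=None, fst_raw=None)
    raw = 1.0 - sw / sb
    return DiversitySummary(
        pi_w, int(len(p1)), n1 + n2, fst=max(0.0, min(1.0, raw)), fst_raw=raw
    )


def site_pair_counts(
    sample: SampleSet,
    maf_min: float = 0.1,
    d_max: float = 20_000,
    max_pairs: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two-locus haplotype counts for all (optionally subsampled) site pairs.

    Returns one row per unordered pair with both minor allele frequencies
    >= ``maf_min`` and 1 <= distance <= ``d_max``: columns n11, n10, n01,
    n00 (derived/ancestral haplotype counts), dist, and the two derived
    allele frequencies.  When ``max_pairs`` is given and fewer pairs than
    candidates are needed, a uniform subsample is drawn with ``rng``.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    H = sample.H
    n = H.shape[0]
    p = H.mean(axis=0)
    maf = np.minimum(p, 1 - p)
    cand = np.flatnonzero((maf >= maf_min) & (maf > 0))
    cols = ["i", "j", "dist", "n11", "n10", "n01", "n00", "p1", "p2", "pos1", "pos2"]
    if len(cand) < 2:
        return pd.DataFrame(columns=cols)
    pos = sample.positions[cand]
    # sorted positions: pairs within d_max form a banded structure
    hi = np.searchsorted(pos, pos + d_max, side="right")
    counts_per_i = hi - np.arange(1, len(pos) + 1)
    offsets = np.concatenate([[0], np.cumsum(counts_per_i)])
    total = int(offsets[-1])
    if total == 0:
        return pd.DataFrame(columns=cols)
    if max_pairs is not None and total > max_pairs:
        rng = rng or np.random.default_rng(0)
        flat = np.sort(rng.choice(total, size=max_pairs, replace=False))
    else:
        flat = np.arange(total)
    ii = np.searchsorted(offsets, flat, side="right") - 1
    jj = ii + 1 + (flat - offsets[ii])
    dist = pos[jj] - pos[ii]
    ok = dist >= 1
    ii, jj, dist = ii[ok], jj[ok], dist[ok]
    A = H[:, cand[ii]].astype(np.int64)
    B = H[:, cand[jj]].astype(np.int64)
    n11 = (A & B).sum(axis=0)
    nA = A.sum(axis=0)
    nB = B.sum(axis=0)
    return pd.DataFrame(
        {
            "i": cand[ii],
            "j": cand[jj],
            "dist": dist,
            "n11": n11,
            "n10": nA - n11,
            "n01": nB - n11,
            "n00": n - nA - nB + n11,
            "p1": nA / n,
            "p2": nB / n,
            "pos1": sample.positions[cand[ii]],
            "pos2": sample.positions[cand[jj]],
        }
    )


def pairwise_ld(
    sample: SampleSet,
    maf_min: float = 0.1,
    d_max: float = 20_000,
    max_pairs: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pairwise LD statistics D, D' and r^2 from phased haplotypes.

    D = p11 - p1*p2 (haplotype-frequency covariance); r^2 = D^2 / (p1 q1
    p2 q2); D' normalizes D by its frequency-constrained extremum.
    Monomorphic input yields an empty frame.
    """
    pairs = site_pair_counts(sample, maf_min, d_max, max_pairs, rng)
    if pairs.empty:
        return pd.DataFrame(
            columns=["dist", "D", "Dprime", "r2", "maf1", "maf2", "p1", "p2"]
        )
    n = sample.n_hap
    p1 = pairs["p1"].to_numpy()
    p2 = pairs["p2"].to_numpy()
    p11 = pairs["n11"].to_numpy() / n
    D = p11 - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    r2 = np.where(denom > 0, D * D / denom, 0.0)
    dmax_pos = np.minimum(p1 * (1 - p2), (1 - p1) * p2)
    dmax_neg = np.minimum(p1 * p2, (1 - p1) * (1 - p2))
    lim = np.where(D >= 0, dmax_pos, dmax_neg)
    dprime = np.where(lim > 0, D / lim, 0.0)
    return pd.DataFrame(
        {
            "dist": pairs["dist"],
            "D": D,
            "Dprime": dprime,
            "r2": r2,
            "maf1": np.minimum(p1, 1 - p1),
            "maf2": np.minimum(p2, 1 - p2),
            "p1": p1,
            "p2": p2,
        }
    )


def island_fst(Nem: float, n_demes: int | None = None) -> float:
    """Equilibrium island-model FST.

    Infinite-island approximation FST = 1/(1 + 4*Nem) when ``n_demes`` is
    None; with a finite deme number k the factor (k/(k-1))^2 applies.
    """
    if Nem < 0:
        raise ValueError("Nem must be non-negative")
    if n_demes is None:
        return 1.0 / (1.0 + 4.0 * Nem)
    if n_demes < 2:
        raise ValueError("need at least two demes")
    c = (n_demes / (n_demes - 1.0)) ** 2
    return 1.0 / (1.0 + 4.0 * Nem * c)


def expected_split_fst(
    theta_anc: float, n_sub: int, mu_site: float, t_gens: float
) -> float:
    """Closed-form Hudson FST trajectory after a clean split with no migration.

    With ancestral diversity theta_anc = 4*N_anc*mu and daughter populations
    of size n_sub: pi_within(t) = theta_sub + (theta_anc - theta_sub) *
    exp(-t / (2*n_sub)), pi_between(t) = theta_anc + 2*mu*t, and
    FST(t) = 1 - pi_w/pi_b.  All quantities in model units.
    """
    theta_sub = 4.0 * n_sub * mu_site
    pi_w = theta_sub + (theta_anc - theta_sub) * math.exp(-t_gens / (2.0 * n_sub))
    pi_b = theta_anc + 2.0 * mu_site * t_gens
    return 1.0 - pi_w / pi_b
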