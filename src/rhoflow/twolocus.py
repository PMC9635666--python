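"""Monte-Carlo two-locus lookup tables under piecewise-constant size history.

The composite-likelihood estimator needs, for a grid of per-pair scaled
recombination rates rho_pair = 4*N*r*d, the probability of every two-locus
haplotype-count configuration (n11, n10, n01, n00) in a sample of
``table_n`` haplotypes, conditional on both loci being biallelic.  These
are estimated by simulating two-locus ancestral histories: lineages carry
ancestral material at one or both loci, coalesce at rate k(k-1)/2 scaled by
the (piecewise-constant) population size of the current epoch, and
both-locus lineages split at rate rho_pair/2.

Conditioning on segregation is done by placing exactly one mutation per
locus uniformly along that locus's marginal-tree branch length, which is
the exact conditional distribution in the small-theta limit (the regime of
per-site theta ~ 0.04 here); a finite-theta rejection mode is retained for
cross-validation.  Configurations are stored folded, i.e. up to allele
relabelling at either locus and locus exchange.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "LookupTable",
    "build_lookup_table",
    "fold_config",
    "enumerate_folded_configs",
    "TableSparsityError",
]


class TableSparsityError(RuntimeError):
    """Raised when a grid point accepts too few Monte-Carlo draws (< 5%)."""


def _images(cfg: tuple[int, int, int, int]):
    c11, c10, c01, c00 = cfg
    base = [
        (c11, c10, c01, c00),
        (c01, c00, c11, c10),  # allele swap at locus A
        (c10, c11, c00, c01),  # allele swap at locus B
        (c00, c01, c10, c11),  # both swaps
    ]
    for b in list(base):
        base.append((b[0], b[2], b[1], b[3]))  # locus exchange
    return base


def fold_config(cfg: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    """Canonical representative under allele-relabelling and locus-exchange."""
    return min(_images(tuple(int(x) for x in cfg)))


@lru_cache(maxsize=8)
def _fold_map(n: int) -> np.ndarray:
    """Flat (c11, cA, cB) code -> folded-config index (0 for invalid codes,
    which never receive weight because marginal trees always segregate)."""
    configs = enumerate_folded_configs(n)
    index = {c: i for i, c in enumerate(configs)}
    out = np.zeros((n + 1) ** 3, dtype=np.int64)
    for c11 in range(n + 1):
        for ca in range(c11, n + 1):
            for cb in range(c11, n + 1):
                c10, c01 = ca - c11, cb - c11
                c00 = n - ca - cb + c11
                if c00 < 0:
                    continue
                if not (1 <= ca <= n - 1) or not (1 <= cb <= n - 1):
                    continue
                code = c11 * (n + 1) * (n + 1) + ca * (n + 1) + cb
                out[code] = index[fold_config((c11, c10, c01, c00))]
    return out


@lru_cache(maxsize=8)
def enumerate_folded_configs(n: int) -> tuple[tuple[int, int, int, int], ...]:
    """All folded configurations of n haplotypes with both loci segregating."""
    out = set()
    for c11 in range(n + 1):
        for c10 in range(n - c11 + 1):
            for c01 in range(n - c11 - c10 + 1):
                c00 = n - c11 - c10 - c01
                if 1 <= c11 + c10 <= n - 1 and 1 <= c11 + c01 <= n - 1:
                    out.add(fold_config((c11, c10, c01, c00)))
    return tuple(sorted(out))


def config_r2(cfg: tuple[int, int, int, int], n: int) -> float:
    c11, c10, c01, c00 = cfg
    pa = (c11 + c10) / n
    pb = (c11 + c01) / n
    D = c11 / n - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    return D * D / denom if denom > 0 else 0.0


@dataclass
class LookupTable:
    """Folded two-locus configuration probabilities over a rho_pair grid."""

    rho_grid: np.ndarray  # strictly increasing, first element 0
    table_n: int
    theta_site: float
    size_history: tuple[tuple[float, float], ...]  # (start_time, rel_size), recent first
    configs: tuple[tuple[int, int, int, int], ...]
    P: np.ndarray  # (n_configs, n_grid), columns sum to 1
    mc_replicates: int
    seed: int
    mode: str = "conditional"
    var_P: np.ndarray | None = None  # per-cell MC variance of P (ratio estimator)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.rho_grid = np.asarray(self.rho_grid, dtype=float)
        if self.rho_grid[0] != 0 or np.any(np.diff(self.rho_grid) <= 0):
            raise ValueError("rho_grid must be strictly increasing and start at 0")
        if self.P.shape != (len(self.configs), len(self.rho_grid)):
            raise ValueError("probability matrix shape mismatch")
        self._index = {c: i for i, c in enumerate(self.configs)}

    def config_index(self, cfg: tuple[int, int, int, int]) -> int:
        return self._index[fold_config(cfg)]

    def expected_r2(self) -> np.ndarray:
        """E[r^2 | rho] across the grid (used for sanity and decay checks)."""
        r2 = np.array([config_r2(c, self.table_n) for c in self.configs])
        return r2 @ self.P

    def log_prob(self) -> np.ndarray:
        """Monte-Carlo-debiased log configuration probabilities.

        ``log P_hat`` underestimates ``log P`` by ~Var(P_hat)/(2 P^2)
        (Jensen); adding the estimated correction back removes the leading
        noise-induced distortion of composite-likelihood surfaces.  Cells
        never hit by the Monte Carlo are floored at half a replicate's
        worth of probability; the correction is capped to keep poorly
        estimated cells from overshooting.
        """
        floor = 0.5 / max(self.mc_replicates, 1)
        logP = np.log(np.maximum(self.P, floor))
        if self.var_P is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = self.var_P / (2.0 * np.maximum(self.P, floor) ** 2)
            logP = logP + np.minimum(np.nan_to_num(corr), 0.7)
        return logP

    # ---- serialization: versioned single-file text archive --------------------
    def save(self, path) -> None:
        header = {
            "format": "rhoflow-lookup",
            "version": 1,
            "table_n": self.table_n,
            "theta_site": self.theta_site,
            "rho_grid": self.rho_grid.tolist(),
            "size_history": [list(e) for e in self.size_history],
            "mc_replicates": self.mc_replicates,
            "seed": self.seed,
            "mode": self.mode,
        }
        with open(path, "w") as fh:
            fh.write("#rhoflow-lookup\t1\n")
            fh.write("#" + json.dumps(header) + "\n")
            var = (
                self.var_P
                if self.var_P is not None
                else np.zeros_like(self.P)
            )
            for cfg, row, vrow in zip(self.configs, self.P, var):
                fh.write(
                    "\t".join(map(str, cfg))
                    + "\t"
                    + "\t".join(f"{v:.10g}" for v in row)
                    + "\t"
                    + "\t".join(f"{v:.6g}" for v in vrow)
                    + "\n"
                )

    @classmethod
    def load(cls, path) -> "LookupTable":
        with open(path) as fh:
            magic = fh.readline()
            if not magic.startswith("#rhoflow-lookup"):
                raise ValueError(f"{path} is not a rhoflow lookup archive")
            header = json.loads(fh.readline().lstrip("#"))
            n_grid = len(header["rho_grid"])
            configs, rows, vrows = [], [], []
            for line in fh:
                parts = line.split("\t")
                configs.append(tuple(int(x) for x in parts[:4]))
                vals = [float(x) for x in parts[4:]]
                rows.append(vals[:n_grid])
                vrows.append(vals[n_grid : 2 * n_grid] if len(vals) >= 2 * n_grid else [0.0] * n_grid)
        return cls(
            rho_grid=np.array(header["rho_grid"]),
            table_n=header["table_n"],
            theta_site=header["theta_site"],
            size_history=tuple(tuple(e) for e in header["size_history"]),
            configs=tuple(configs),
            P=np.array(rows),
            mc_replicates=header["mc_replicates"],
            seed=header["seed"],
            mode=header.get("mode", "conditional"),
            var_P=np.array(vrows),
        )


def simulate_two_locus(
    n: int,
    rho_pair: float,
    size_history,
    rng: np.random.Generator,
    theta_locus: float | None = None,
    record: bool = False,
):
    """One two-locus ancestral history; returns derived-carrier leaf masks.

    Returns ``(mask_a, mask_b, T_a, T_b)``: bitmasks of the haplotypes
    carrying the derived allele at each locus (one mutation per locus placed
    uniformly along that locus's marginal branch length) plus the two
    marginal total branch lengths.  In the small-theta limit the probability
    of observing exactly one mutation at each locus is proportional to
    ``T_a * T_b``, so tabulating with that importance weight gives the exact
    conditional configuration distribution; weighting a single locus by its
    own ``T`` recovers the neutral frequency spectrum (proportional to 1/i).
    In rejection mode (``theta_locus`` given) returns None unless a
    Poisson(theta/2 * T) draw yields exactly one mutation at each locus —
    the thinning then supplies the weight.  Time is measured in units of
    2*N_present generations; epoch sizes in ``size_history`` are relative to
    the present size.

    With ``record=True`` the full branch-segment lists are returned instead:
    ``(segs_a, segs_b)``, each a list of ``(leaf_mask, length)`` entries
    covering the locus's marginal tree.  Tabulating every segment pair with
    weight ``len_a * len_b`` is the Rao-Blackwellized version of the
    single-placement scheme and converges far faster per genealogy.
    """
    full = (1 << n) - 1
    mask_a = [1 << i for i in range(n)]
    mask_b = [1 << i for i in range(n)]
    birth = [0.0] * n
    n_both = n
    done_a = done_b = False
    tot_a = tot_b = 0.0
    chosen_a = chosen_b = 0
    segs_a: list[tuple[int, float]] = []
    segs_b: list[tuple[int, float]] = []
    t = 0.0
    epochs = list(size_history)
    e = 0

    def close_out(i: int, now: float) -> None:
        nonlocal tot_a, tot_b, chosen_a, chosen_b
        seg = now - birth[i]
        if seg > 0:
            if not done_a and mask_a[i]:
                tot_a += seg
                if record:
                    segs_a.append((mask_a[i], seg))
                elif rng.random() < seg / tot_a:
                    chosen_a = mask_a[i]
            if not done_b and mask_b[i]:
                tot_b += seg
                if record:
                    segs_b.append((mask_b[i], seg))
                elif rng.random() < seg / tot_b:
                    chosen_b = mask_b[i]

    while not (done_a and done_b):
        k = len(mask_a)
        size = epochs[e][1]
        c_rate = k * (k - 1) / 2.0 / size
        r_rate = 0.5 * rho_pair * n_both
        rate = c_rate + r_rate
        dt = rng.exponential(1.0 / rate)
        boundary = epochs[e + 1][0] if e + 1 < len(epochs) else np.inf
        if t + dt > boundary:
            t = boundary
            e += 1
            continue
        t += dt
        if rng.random() < c_rate / rate:
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            close_out(i, t)
            close_out(j, t)
            ma = mask_a[i] | mask_a[j]
            mb = mask_b[i] | mask_b[j]
            if (mask_a[i] and mask_b[i]):
                n_both -= 1
            if (mask_a[j] and mask_b[j]):
                n_both -= 1
            if done_a:
                ma = 0
            if done_b:
                mb = 0
            if ma == full:
                done_a = True
                ma = 0
            if mb == full:
                done_b = True
                mb = 0
            # overwrite i with the merged lineage, swap-remove j
            hi, lo = max(i, j), min(i, j)
            for arr in (mask_a, mask_b, birth):
                arr[hi] = arr[-1]
                arr.pop()
            if ma or mb:
                mask_a[lo], mask_b[lo], birth[lo] = ma, mb, t
                if ma and mb:
                    n_both += 1
            else:
                for arr in (mask_a, mask_b, birth):
                    arr[lo] = arr[-1]
                    arr.pop()
        else:
            # recombination: a both-locus lineage splits into A-only + B-only
            target = int(rng.integers(n_both))
            idx = -1
            for i in range(k):
                if mask_a[i] and mask_b[i]:
                    idx += 1
                    if idx == target:
                        idx = i
                        break
            close_out(idx, t)
            mb = mask_b[idx]
            mask_b[idx] = 0
            birth[idx] = t
            mask_a.append(0)
            mask_b.append(mb)
            birth.append(t)
            n_both -= 1

    if record:
        return segs_a, segs_b
    if theta_locus is not None:
        if rng.poisson(0.5 * theta_locus * tot_a) != 1:
            return None
        if rng.poisson(0.5 * theta_locus * tot_b) != 1:
            return None
    return chosen_a, chosen_b, tot_a, tot_b


def build_lookup_table(
    table_n: int,
    theta_site: float,
    rho_grid,
    size_history,
    mc_replicates: int,
    seed: int,
    *,
    mode: str = "conditional",
    theta_locus: float = 0.05,
) -> LookupTable:
    """Estimate folded configuration probabilities at every grid point.

    ``mode="conditional"`` (default) places one mutation per locus uniformly
    on the marginal branch lengths — every draw is accepted.  In
    ``mode="rejection"`` draws are thinned by a Poisson(theta_locus/2 * T)
    "exactly one mutation" test at each locus; a grid point accepting fewer
    than 5% of draws raises :class:`TableSparsityError`.
    """
    if table_n < 4 or table_n % 2:
        raise ValueError("table_n must be an even integer >= 4")
    rho_grid = np.asarray(rho_grid, dtype=float)
    if len(rho_grid) == 0 or rho_grid[0] != 0 or np.any(np.diff(rho_grid) <= 0):
        raise ValueError("rho_grid must start at 0 and increase strictly")
    size_history = tuple((float(t), float(s)) for t, s in size_history)
    if not size_history or size_history[0][0] != 0:
        raise ValueError("size_history must be non-empty and start at time 0")
    if mode not in ("conditional", "rejection"):
        raise ValueError(f"unknown mode {mode!r}")

    n = table_n
    configs = enumerate_folded_configs(n)
    index = {c: i for i, c in enumerate(configs)}
    P = np.zeros((len(configs), len(rho_grid)))
    var_P = np.zeros_like(P)
    for g, rho in enumerate(rho_grid):
        # common random numbers across grid columns: neighbouring rho values
        # see strongly correlated genealogies, so Monte-Carlo noise enters the
        # composite-likelihood surface as a smooth shared deformation rather
        # than column-to-column jitter of the argmax
        rng = np.random.default_rng(seed)
        if mode == "conditional":
            # Rao-Blackwellized tabulation: every (branch_a, branch_b) pair of
            # each genealogy contributes weight len_a * len_b, the joint
            # probability mass of one mutation landing on each branch.
            # Per-replicate folding also yields the ratio-estimator variance
            # of each cell, used downstream for Jensen de-biasing of log P.
            s1 = np.zeros(len(configs))
            s2 = np.zeros(len(configs))
            sc = np.zeros(len(configs))
            t1 = 0.0
            t2 = 0.0
            for _ in range(mc_replicates):
                segs_a, segs_b = simulate_two_locus(
                    n, rho, size_history, rng, record=True
                )
                m_a = np.array([s[0] for s in segs_a], dtype=np.uint64)
                l_a = np.array([s[1] for s in segs_a])
                m_b = np.array([s[0] for s in segs_b], dtype=np.uint64)
                l_b = np.array([s[1] for s in segs_b])
                c11 = np.bitwise_count(m_a[:, None] & m_b[None, :]).astype(np.int64)
                ca = np.bitwise_count(m_a).astype(np.int64)[:, None]
                cb = np.bitwise_count(m_b).astype(np.int64)[None, :]
                codes = c11 * (n + 1) * (n + 1) + ca * (n + 1) + cb
                w = l_a[:, None] * l_b[None, :]
                wr = np.bincount(
                    _fold_map(n)[codes.ravel()], weights=w.ravel(),
                    minlength=len(configs),
                )
                tr = wr.sum()
                s1 += wr
                s2 += wr * wr
                sc += wr * tr
                t1 += tr
                t2 += tr * tr
            P[:, g] = s1 / t1
            var = (s2 - 2.0 * P[:, g] * sc + P[:, g] ** 2 * t2) / (t1 * t1)
            var_P[:, g] = np.maximum(var, 0.0)
        else:
            weights = np.zeros(len(configs))
            accepted = 0
            for _ in range(mc_replicates):
                res = simulate_two_locus(n, rho, size_history, rng, theta_locus)
                if res is None:
                    continue
                da, db, ta, tb = res
                c11 = (da & db).bit_count()
                c10 = da.bit_count() - c11
                c01 = db.bit_count() - c11
                weights[index[fold_config((c11, c10, c01, n - c11 - c10 - c01))]] += 1.0
                accepted += 1
            if accepted < 0.05 * mc_replicates:
                raise TableSparsityError(
                    f"grid point rho_pair={rho:g}: {accepted}/{mc_replicates} draws accepted"
                )
            P[:, g] = weights / weights.sum()
    return LookupTable(
        rho_grid=rho_grid,
        table_n=table_n,
        theta_site=theta_site,
        size_history=size_history,
        configs=configs,
        P=P,
        mc_replicates=mc_replicates,
        seed=seed,
        mode=mode,
        var_P=var_P if mode == "conditional" else None,
    )


def default_rho_grid(rho_max: float = 200.0, n_points: int = 15) -> np.ndarray:
    """0 plus log-spaced per-pair rho values covering 0.1 .. rho_max."""
    return np.concatenate([[0.0], np.geomspace(0.1, rho_max, n_points)])
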