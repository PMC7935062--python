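"""Hartigan–Hartigan dip statistic and a bootstrap unimodality test.

The dip of an empirical CDF :math:`F_n` is the smallest sup-norm distance

.. math:: D(F_n) = \\min_{G\\ \\mathrm{unimodal}} \\; \\sup_x |F_n(x) - G(x)|

over unimodal distribution functions (convex below the mode, concave above
it, with an atom permitted at the mode).  Large values indicate
multimodality.  For a sample of :math:`n` distinct points the dip lies in
:math:`[1/(2n),\\ 1/4]`, the upper bound being attained by an even two-point
mixture.

The implementation scans candidate mode locations over the data values.
At each data point the CDF constrains any approximating :math:`G` to a
vertical band, two-sided at the mode and one-sided elsewhere.  For a fixed
mode, feasibility of threading a convex limb (via the greatest convex
minorant of the band floor) and a concave limb (least concave majorant of
the band ceiling, by mirror symmetry) gives a closed-form minimal distance;
a remaining coupling condition — the left limb's forced endpoint must not
exceed the right limb's forced start — is resolved exactly by pivoting on
two-anchor chord-extension certificates, which are linear in the distance.
The result is exact to floating-point precision (it agrees with a
brute-force minimax over unimodal step CDFs; see the test suite).
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError

__all__ = ["dip_statistic", "dip_test"]


def _bands(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique sorted values with the CDF's left and right limits there."""
    u, counts = np.unique(x, return_counts=True)
    hi = np.cumsum(counts) / x.size
    lo = np.concatenate(([0.0], hi[:-1]))
    return u, lo, hi


def _limb_ts(u: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Minimal t making the convex limb ending at each index feasible.

    The limb on 0..j needs a convex nondecreasing curve with
    ``C_i >= hi_i - t`` (``lo_j - t`` at the mode j) and ``C_i <= lo_i + t``.
    The maximal convex curve under the ceiling is ``GCM(lo) + t``, so the
    limb is feasible iff ``t >= max_i (floor_i - GCM(lo)_i) / 2``.  The GCM
    is grown incrementally with a monotone hull stack.
    """
    m = u.size
    out = np.zeros(m)
    stack: list[int] = []
    for j in range(m):
        while len(stack) >= 2:
            i, k = stack[-2], stack[-1]
            if (lo[k] - lo[i]) * (u[j] - u[i]) >= (lo[j] - lo[i]) * (u[k] - u[i]):
                stack.pop()
            else:
                break
        stack.append(j)
        idx = np.asarray(stack)
        G = np.interp(u[:j + 1], u[idx], lo[idx])
        dev = np.max(np.concatenate([hi[:j] - G[:j], [lo[j] - G[j]]]))
        out[j] = 0.5 * max(0.0, float(dev))
    return out


def dip_statistic(values) -> float:
    """Dip statistic of a one-dimensional sample.

    Parameters
    ----------
    values
        At least 4 finite observations (ties allowed).

    Returns
    -------
    float
        The dip; within ``[1/(2n), 1/4]`` for samples with distinct values.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("values must be finite")
    if x.size < 4:
        raise InsufficientDataError(f"need >= 4 values, got {x.size}")
    u, lo, hi = _bands(np.sort(x))
    m = u.size
    if m == 1:
        return 0.0
    tL = _limb_ts(u, lo, hi)
    # right limb by the mirror x -> -x, F -> 1 - F
    tR = _limb_ts(-u[::-1], (1.0 - hi)[::-1], (1.0 - lo)[::-1])[::-1]

    best = np.inf
    for j in range(m):
        t = max(tL[j], tR[j])
        if t >= best:
            continue
        # left coupling certificates: a low anchor at i1 (<= lo_i1 + t)
        # followed by a forced-high anchor at i2 (>= hi_i2 - t) makes the
        # convex extension to the mode at least beta(t), linear decreasing.
        if j >= 2:
            i1g, i2g = np.meshgrid(np.arange(j - 1), np.arange(1, j),
                                   indexing="ij")
            mask = i1g < i2g
            r = (u[j] - u[i2g]) / np.where(mask, u[i2g] - u[i1g], np.inf)
            bc = (hi[i2g] + (hi[i2g] - lo[i1g]) * r)[mask]
            bs = -(1.0 + 2.0 * r)[mask]
        else:
            bc = bs = np.empty(0)
        # right coupling certificates (mirror): gp_max(t), linear increasing
        if j <= m - 3:
            i3g, i4g = np.meshgrid(np.arange(j + 1, m - 1),
                                   np.arange(j + 2, m), indexing="ij")
            mask = i3g < i4g
            s = (u[i3g] - u[j]) / np.where(mask, u[i4g] - u[i3g], np.inf)
            gc = (lo[i3g] - (hi[i4g] - lo[i3g]) * s)[mask]
            gs = (1.0 + 2.0 * s)[mask]
        else:
            gc = gs = np.empty(0)

        for _ in range(100):
            gm, sa = lo[j] - t, -1.0
            if bc.size:
                vals = bc + bs * t
                k = int(np.argmax(vals))
                if vals[k] > gm:
                    gm, sa = vals[k], bs[k]
            gp, sb = hi[j] + t, 1.0
            if gc.size:
                vals = gc + gs * t
                k = int(np.argmin(vals))
                if vals[k] < gp:
                    gp, sb = vals[k], gs[k]
            if gm <= gp + 1e-14:
                break
            t += (gm - gp) / (sb - sa)
        best = min(best, t)
    return float(best)


_NULL_CACHE: dict[tuple[int, int, int | None], np.ndarray] = {}


def _null_dips(n: int, n_boot: int, seed) -> np.ndarray:
    """Dips of ``n_boot`` uniform(0,1) samples of size ``n`` (cached)."""
    key = (n, n_boot, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(None if seed is None
                                    else [int(seed), n, n_boot, 0x_D1B])
        _NULL_CACHE[key] = np.array(
            [dip_statistic(rng.uniform(0.0, 1.0, n)) for _ in range(n_boot)])
        if len(_NULL_CACHE) > 64:
            _NULL_CACHE.pop(next(iter(_NULL_CACHE)))
    return _NULL_CACHE[key]


def dip_test(values, n_boot: int = 200, seed: int | None = None) -> float:
    """Bootstrap p-value for unimodality via the dip statistic.

    The observed dip is compared against dips of uniform(0,1) samples of
    the same size — the conventional calibrating distribution, which is the
    least-favourable unimodal case.  Tied observations (ordinal plumage
    classes) are first jittered uniformly on ``[v - 0.5, v + 0.5]`` with a
    seeded draw so the statistic sees a continuous sample.

    Parameters
    ----------
    values
        Sample of at least 4 observations.
    n_boot
        Number of uniform reference samples (>= 100).
    seed
        Seeds both the tie-breaking jitter and the reference samples;
        identical ``(values, n_boot, seed)`` give identical p-values.

    Returns
    -------
    float
        Fraction of reference dips at least as large as the observed dip.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size < 4:
        raise InsufficientDataError(f"need >= 4 values, got {x.size}")
    if n_boot < 100:
        raise InvalidArgumentError("n_boot must be >= 100")
    # sorting first makes the jitter (hence the p-value) invariant to the
    # order in which specimens were recorded
    if np.unique(x).size < x.size:
        rng = np.random.default_rng(None if seed is None
                                    else [int(seed), x.size, 0x_71E])
        x = x + rng.uniform(-0.5, 0.5, x.size)
    observed = dip_statistic(x)
    null = _null_dips(x.size, n_boot, seed)
    return float(np.mean(null >= observed))
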