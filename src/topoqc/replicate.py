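"""Replicate-consistency filtering: k-sample Anderson-Darling + SNR.

Each topography design occupies replicate TopoUnits; a design is kept only
when its replicates both (a) follow the same value distribution — tested
with the k-sample Anderson-Darling statistic of Scholz & Stephens (midrank
version, robust to ties), retained when the approximate p-value exceeds the
lower band edge (default p > 0.05) — and (b) show a stable signal-to-noise
ratio |mean| / SD inside an acceptance band (default 2 < SNR < 20; the upper
bound guards against suspiciously noise-free, likely-degenerate surfaces
and is a documented screen convention).

The AD statistic and its normalized form are implemented here from the
Scholz-Stephens formulas; a seeded permutation (or exhaustive-enumeration)
p-value is available as the reference oracle for the tabulated asymptotic
approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ADResult",
    "ad_ksample",
    "ad_permutation_pvalue",
    "SNRResult",
    "snr",
    "FilterReport",
    "DualReplicateFilter",
    "dual_filter",
    "removal_report",
]


@dataclass(frozen=True)
class ADResult:
    """k-sample Anderson-Darling outcome.

    ``statistic`` is the midrank A2_akN; ``normalized`` is the standardized
    form (A2 - (k-1)) / sigma_N whose null distribution the p-value
    approximation interpolates.
    """

    statistic: float
    normalized: float
    n_samples: int
    total_n: int
    p_value: float


def _check_samples(samples):
    arrays = [np.asarray(s, dtype=float).ravel() for s in samples]
    if len(arrays) < 2:
        raise ValueError("need at least 2 samples")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"sample {i} has {a.size} < 2 values")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"sample {i} contains non-finite values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError(
            "degenerate input: all pooled values are identical; the AD "
            "statistic is undefined")
    return arrays, pooled


def _ad_statistic_midrank(arrays, pooled) -> float:
    """Scholz-Stephens A2_akN with midrank treatment of ties."""
    N = pooled.size
    z_star, counts = np.unique(pooled, return_counts=True)
    L = z_star.size
    lj = counts.astype(float)
    # B_aj: pooled count strictly below z*_j plus half the ties at z*_j
    cum = np.concatenate(([0.0], np.cumsum(lj)))[:L]
    Baj = cum + lj / 2.0
    inner_sum = 0.0
    for a in arrays:
        ni = a.size
        # f_ij: multiplicity of z*_j in sample i
        idx = np.searchsorted(z_star, np.sort(a))
        fij = np.bincount(idx, minlength=L).astype(float)
        cum_i = np.concatenate(([0.0], np.cumsum(fij)))[:L]
        Maij = cum_i + fij / 2.0
        num = (N * Maij - ni * Baj) ** 2
        den = Baj * (N - Baj) - N * lj / 4.0
        term = np.where(den > 0, lj / N * num / np.where(den > 0, den, 1.0),
                        0.0)
        inner_sum += term.sum() / ni
    return (N - 1.0) / N * inner_sum


def _ad_variance(k: int, sample_sizes) -> float:
    """Null variance of A2_kN (Scholz-Stephens)."""
    N = int(sum(sample_sizes))
    H = sum(1.0 / n for n in sample_sizes)
    inv = 1.0 / np.arange(1, N)          # 1/1 .. 1/(N-1)
    cum = np.cumsum(inv)
    h = float(cum[-1])                   # sum_{i=1}^{N-1} 1/i
    i = np.arange(1, N - 1)
    # g = sum_{i=1}^{N-2} (1/(N-i)) * sum_{j=i+1}^{N-1} 1/j
    g = float(np.sum((h - cum[i - 1]) / (N - i)))
    a = (4.0 * g - 6.0) * (k - 1) + (10.0 - 6.0 * g) * H
    b = (2.0 * g - 4.0) * k**2 + 8.0 * h * k \
        + (2.0 * g - 14.0 * h - 4.0) * H - 8.0 * h + 4.0 * g - 6.0
    c = (6.0 * h + 2.0 * g - 2.0) * k**2 + (4.0 * h - 4.0 * g + 6.0) * k \
        + (2.0 * h - 6.0) * H + 4.0 * h
    d = (2.0 * h + 6.0) * k**2 - 4.0 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0)
                                               * (N - 3.0))
    return var


# Scholz-Stephens critical values of the normalized statistic:
# tm(alpha) = b0 + b1/sqrt(m) + b2/m with m = k - 1.
_AD_ALPHAS = np.array([0.25, 0.10, 0.05, 0.025, 0.01])
_AD_B0 = np.array([0.675, 1.281, 1.645, 1.960, 2.326])
_AD_B1 = np.array([-0.245, 0.250, 0.678, 1.149, 1.822])
_AD_B2 = np.array([-0.105, -0.305, -0.362, -0.391, -0.396])


def _ad_pvalue(normalized: float, k: int) -> float:
    """Interpolate log(alpha) quadratically through the tabulated critical
    values of the normalized statistic (extrapolated beyond the table,
    clipped to [1e-4, 1])."""
    m = k - 1
    tm = _AD_B0 + _AD_B1 / math.sqrt(m) + _AD_B2 / m
    a, b, c = np.polyfit(tm, np.log(_AD_ALPHAS), 2)
    t = normalized
    if a > 0:
        # keep log(p) monotone decreasing beyond the fitted range: evaluate
        # at the parabola's minimum for any larger statistic
        t = min(t, -b / (2 * a))
    p = math.exp(float(np.polyval([a, b, c], t)))
    return float(min(max(p, 1e-4), 1.0))


def ad_ksample(samples) -> ADResult:
    """k-sample Anderson-Darling test (Scholz-Stephens, midrank ties).

    A small p-value means the replicate samples do not share one
    distribution. Requires k >= 2 samples of >= 2 values each and a
    non-degenerate pooled sample.
    """
    arrays, pooled = _check_samples(samples)
    k = len(arrays)
    stat = _ad_statistic_midrank(arrays, pooled)
    sigma = math.sqrt(_ad_variance(k, [a.size for a in arrays]))
    normalized = (stat - (k - 1)) / sigma
    return ADResult(
        statistic=float(stat),
        normalized=float(normalized),
        n_samples=k,
        total_n=int(pooled.size),
        p_value=_ad_pvalue(normalized, k),
    )


def ad_permutation_pvalue(samples, n_permutations: int = 10_000,
                          seed: int = 0, exact_limit: int = 20_000) -> float:
    """Permutation p-value of the midrank AD statistic (reference oracle).

    When the number of distinct assignments of pooled values to samples is
    at most ``exact_limit`` (and there are 2 samples), all assignments are
    enumerated; otherwise ``n_permutations`` seeded shuffles are drawn.
    The p-value uses the add-one rule P((#>= observed) + 1) / (n + 1) in the
    sampled case and the exact proportion in the enumerated case.
    """
    arrays, pooled = _check_samples(samples)
    sizes = [a.size for a in arrays]
    observed = _ad_statistic_midrank(arrays, pooled)
    N = pooled.size

    if len(arrays) == 2 and math.comb(N, sizes[0]) <= exact_limit:
        count = 0
        total = 0
        idx_all = range(N)
        for combo in itertools.combinations(idx_all, sizes[0]):
            mask = np.zeros(N, dtype=bool)
            mask[list(combo)] = True
            stat = _ad_statistic_midrank([pooled[mask], pooled[~mask]],
                                         pooled)
            total += 1
            if stat >= observed - 1e-12:
                count += 1
        return count / total

    rng = np.random.default_rng(seed)
    count = 0
    bounds = np.cumsum(sizes)[:-1]
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        parts = np.split(perm, bounds)
        stat = _ad_statistic_midrank(parts, pooled)
        if stat >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNRResult:
    """Signal-to-noise of replicate measurements: |mean| / SD (n-1)."""

    mean: float
    sd: float

    @property
    def snr(self) -> float:
        if self.sd == 0:
            return float("inf")
        return abs(self.mean) / self.sd


def snr(values) -> SNRResult:
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError(f"need at least 2 values for SNR, got {v.size}")
    return SNRResult(mean=float(v.mean()), sd=float(v.std(ddof=1)))


# ---------------------------------------------------------------------------
# dual filter
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Removal accounting of the dual AD/SNR filter for one feature."""

    feature: str
    ad_band: tuple
    snr_band: tuple
    removed_by_ad: list = field(default_factory=list)
    removed_by_snr: list = field(default_factory=list)
    untestable: list = field(default_factory=list)
    n_designs: int = 0

    @property
    def removed_union(self) -> list:
        return sorted(set(self.removed_by_ad) | set(self.removed_by_snr))

    def to_row(self) -> dict:
        return {
            "feature": self.feature,
            "removed_by_ad": len(self.removed_by_ad),
            "removed_by_snr": len(self.removed_by_snr),
            "removed_total": len(self.removed_union),
            "untestable": len(self.untestable),
            "n_designs": self.n_designs,
            "ad_band": f"({self.ad_band[0]}; {self.ad_band[1]})",
            "snr_band": f"({self.snr_band[0]}; {self.snr_band[1]})",
        }


class DualReplicateFilter(BaseEstimator):
    """Dual Anderson-Darling + SNR reproducibility filter over designs.

    ``fit`` evaluates, for every design, the AD test across its replicate
    value groups and the SNR of the pooled values; a design is removed when
    the AD p-value falls outside ``ad_band`` (retain iff p > lower edge) OR
    the SNR falls outside the open interval ``snr_band``. Both criteria are
    evaluated on the full design set in parallel (not sequentially), and the
    per-criterion removals plus their union are reported.

    Designs with fewer than 2 replicate groups (or any group of fewer than
    2 values) are flagged "untestable" — neither retained nor silently
    removed.
    """

    def __init__(self, ad_band=(0.05, 1.0), snr_band=(2.0, 20.0),
                 feature: str = "value"):
        self.ad_band = ad_band
        self.snr_band = snr_band
        self.feature = feature

    def fit(self, replicates: dict, y=None):
        """``replicates`` maps design_id -> sequence of replicate value
        groups (each an array of measurements)."""
        report = FilterReport(feature=self.feature,
                              ad_band=tuple(self.ad_band),
                              snr_band=tuple(self.snr_band),
                              n_designs=len(replicates))
        p_lo, _ = self.ad_band
        s_lo, s_hi = self.snr_band
        retained = []
        results = {}
        for design, groups in replicates.items():
            groups = [np.asarray(g, dtype=float).ravel() for g in groups]
            groups = [g for g in groups if g.size > 0]
            pooled = (np.concatenate(groups) if groups
                      else np.empty(0))
            if len(groups) < 2 or any(g.size < 2 for g in groups) \
                    or pooled.size < 2:
                report.untestable.append(design)
                continue
            try:
                ad = ad_ksample(groups)
                p = ad.p_value
            except ValueError:
                # degenerate pooled values: distributions identical
                ad = None
                p = 1.0
            s = snr(pooled).snr
            results[design] = {"p_value": p, "snr": s}
            bad_ad = not (p > p_lo)
            bad_snr = not (s_lo < s < s_hi)
            if bad_ad:
                report.removed_by_ad.append(design)
            if bad_snr:
                report.removed_by_snr.append(design)
            if not bad_ad and not bad_snr:
                retained.append(design)
        self.report_ = report
        self.results_ = results
        self.retained_ = sorted(retained)
        return self


def dual_filter(replicates: dict, feature: str = "value",
                ad_band=(0.05, 1.0), snr_band=(2.0, 20.0)):
    """Functional form of :class:`DualReplicateFilter`.

    Returns ``(retained_design_ids, FilterReport)``.
    """
    f = DualReplicateFilter(ad_band=ad_band, snr_band=snr_band,
                            feature=feature).fit(replicates)
    return f.retained_, f.report_


def replicate_groups_from_cells(cells: pd.DataFrame, layout,
                                feature: str = "nuclear_area",
                                mode: str = "cells") -> dict:
    """Build design -> replicate value groups from a cell table.

    ``mode='cells'`` (default): two groups per design, the cell-level values
    of its two duplicate positions pooled across chips. ``mode='units'``:
    groups are the per-chip unit means of each duplicate position.
    """
    if mode not in ("cells", "units"):
        raise ValueError(f"unknown replicate grouping mode {mode!r}")
    out = {}
    key = cells.groupby(["row", "col"], sort=True)
    by_pos = {pos: grp for pos, grp in key}
    for design in layout.design_ids:
        groups = []
        for pos in layout.positions_of(design):
            grp = by_pos.get(pos)
            if grp is None:
                continue
            if mode == "cells":
                groups.append(grp[feature].to_numpy(dtype=float))
            else:
                groups.append(
                    grp.groupby("chip_id")[feature].mean().to_numpy())
        out[design] = groups
    return out


def removal_report(reports) -> pd.DataFrame:
    """Per-feature removal table (one row per feature, columns for the AD
    band and SNR band removal counts)."""
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one feature report")
    return pd.DataFrame([r.to_row() for r in reports])


def removal_report_text(reports) -> str:
    frame = removal_report(reports)
    lines = ["Number of removed surfaces",
             f"{'Feature':<24}{'AD ' + str(frame['ad_band'][0]):<18}"
             f"{'SNR ' + str(frame['snr_band'][0])}"]
    for _, row in frame.iterrows():
        lines.append(f"{row['feature']:<24}{row['removed_by_ad']:<18}"
                     f"{row['removed_by_snr']}")
    return "\n".join(lines)
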