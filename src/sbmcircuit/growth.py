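"""Cumulative daily circuits and per-class growth percentages.

The day-i circuit contains the neurons born on day i or earlier; class
growth on day i is the percentage difference between the class's actual
size and the size expected if the final class proportions were uniformly
scaled down to the day's neuron count:

    g_k^i = 100 * (n_i * rho_k^i - n_i * rho_k^final) / (n_i * rho_k^final)

Days whose day-over-day change in g ranks in the top quartile form the
class's critical growth period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sbmcircuit.synth import BIRTHTIMES


@dataclass
class DailySeries:
    """Class composition of the cumulative circuit on one day."""

    day: int  # 0 = embryo, 1..9 = day1..day9
    n: int  # cumulative assigned-neuron count
    rho: np.ndarray = field(repr=False)  # class proportions, sums to 1

    @property
    def class_sizes(self) -> np.ndarray:
        return self.n * self.rho


@dataclass
class GrowthProfile:
    """Percentage growth per class and day; NaN where undefined."""

    g: np.ndarray = field(repr=False)  # kappa x n_days
    days: tuple = tuple(range(len(BIRTHTIMES)))


def _day_index(birthtimes) -> np.ndarray:
    lookup = {name: i for i, name in enumerate(BIRTHTIMES)}
    try:
        return np.array([lookup[str(b)] for b in birthtimes])
    except KeyError as exc:
        raise ValueError(f"unknown birthtime {exc.args[0]!r}") from None


def build_daily_series(labels: np.ndarray, birthtimes) -> list[DailySeries]:
    """One :class:`DailySeries` per day, over assigned neurons only.

    ``labels`` are consensus classes (0 = unassigned, excluded);
    ``birthtimes`` must name one of ``("embryo", "day1", ..., "day9")``
    for every neuron.
    """
    labels = np.asarray(labels)
    birthtimes = np.asarray(birthtimes, dtype=object)
    if labels.shape != birthtimes.shape:
        raise ValueError("labels and birthtimes must align")
    if any(b is None or (isinstance(b, float) and np.isnan(b)) for b in birthtimes):
        raise ValueError("every neuron needs a birthtime")
    day_of = _day_index(birthtimes)
    kappa = int(labels.max())
    series = []
    for day in range(len(BIRTHTIMES)):
        mask = (day_of <= day) & (labels > 0)
        n_i = int(mask.sum())
        counts = np.bincount(labels[mask], minlength=kappa + 1)[1:].astype(float)
        rho = counts / n_i if n_i else np.zeros(kappa)
        series.append(DailySeries(day=day, n=n_i, rho=rho))
    return series


def growth_percentages(series: list[DailySeries]) -> GrowthProfile:
    """Apply the uniform-growth comparison to a daily series.

    Requires every class to be present on the final day (otherwise the
    reference size is zero and the entry is undefined/NaN).
    """
    if len(series) < 2:
        raise ValueError("need at least 2 days")
    rho_final = series[-1].rho
    kappa = rho_final.size
    g = np.full((kappa, len(series)), np.nan)
    for col, day in enumerate(series):
        ok = rho_final > 0
        g[ok, col] = 100.0 * (day.rho[ok] - rho_final[ok]) / rho_final[ok]
    return GrowthProfile(g=g, days=tuple(s.day for s in series))


def critical_periods(profile: GrowthProfile, top_fraction: float = 0.25) -> list[list[int]]:
    """Days in the top quartile of day-over-day growth-rate change, per class.

    The day-0 rate is taken as ``g_k^0 - 0`` (growth from nothing); each
    later day uses ``g_k^i - g_k^{i-1}``. Ties at the quartile boundary
    share rank and are all flagged.
    """
    g = profile.g
    kappa, n_days = g.shape
    if n_days < 2:
        raise ValueError("need at least 2 days")
    out = []
    for k in range(kappa):
        diffs = np.empty(n_days)
        diffs[0] = g[k, 0]
        diffs[1:] = np.diff(g[k])
        valid = ~np.isnan(diffs)
        if not valid.any():
            out.append([])
            continue
        thresh = np.quantile(diffs[valid], 1.0 - top_fraction, method="higher")
        flagged = [profile.days[i] for i in range(n_days) if valid[i] and diffs[i] >= thresh]
        out.append(flagged)
    return out
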