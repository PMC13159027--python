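"""Subject-level and grand-averaged correlation maps.

Three comparison levels are supported, all operating on aligned
band-limited amplitude envelopes:

* within-subject — viewing 1 vs viewing 2 of the same subject;
* between-subject — each subject's viewings against the alternate
  viewings of every other subject in the cohort (bidirectional), averaged
  to one entry per subject;
* between-method — every (subject, viewing) of one cohort against the
  alternate viewing of every subject of a second cohort; an electrode
  montage pooled across patients participates as a single subject and is
  compared with Spearman rank correlations.

Correlations are Fisher z-transformed before any averaging; a grand
average (GA) is the mean Fisher-z per channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EnvelopeSet, Recording
from .filters import resample

__all__ = [
    "ComparisonSpec",
    "CorrelationSet",
    "GrandAverage",
    "correlate_pair",
    "fisher_z",
    "within_subject_set",
    "between_subject_set",
    "between_method_set",
    "grand_average",
    "temporal_resolution_sensitivity",
]

_CLAMP = 1.0 - 1e-12


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform (atanh), clamping |r| = 1 to 1 - 1e-12.

    Perfect correlations only arise in degenerate fixtures (identical
    series); clamping keeps them finite instead of crashing.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| >= 1 clamped before Fisher transform", RuntimeWarning, stacklevel=2)
        r = np.clip(r, -_CLAMP, _CLAMP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variance)."""


def correlate_pair(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Pearson product-moment or Spearman rank (average-rank ties)
    correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance series")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    x = x - x.mean()
    y = y - y.mean()
    return float(np.clip((x @ y) / np.sqrt((x @ x) * (y @ y)), -1.0, 1.0))


def channel_correlations(X: np.ndarray, Y: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Per-channel correlation of two channels x samples arrays.

    Zero-variance channels yield NaN (masked downstream rather than raising).
    """
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        Y = stats.rankdata(Y, axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.einsum("ct,ct->c", Xc, Yc)
    denom = np.sqrt(np.einsum("ct,ct->c", Xc, Xc) * np.einsum("ct,ct->c", Yc, Yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


@dataclass
class ComparisonSpec:
    """One comparison: level, participating cohort(s), band, and options."""

    level: str  # within_subject | between_subject | between_method
    cohort_a: EnvelopeSet
    band: str
    cohort_b: EnvelopeSet | None = None
    pairing: str = "cross_viewing"  # or within_viewing
    method: str | None = None  # None -> inferred
    two_stage_average: bool = False  # between-method: average per cohort-a subject first

    def __post_init__(self) -> None:
        if self.level not in ("within_subject", "between_subject", "between_method"):
            raise ValueError(f"unknown comparison level {self.level!r}")
        if self.pairing not in ("cross_viewing", "within_viewing"):
            raise ValueError(f"unknown pairing {self.pairing!r}")
        if self.level == "between_method" and self.cohort_b is None:
            raise ValueError("between_method needs two cohorts")
        if self.level != "between_method" and self.cohort_b is not None:
            raise ValueError(f"{self.level} takes a single cohort")
        if self.method is None:
            montage = self.cohort_a.modality == "montage" or (
                self.cohort_b is not None and self.cohort_b.modality == "montage"
            )
            self.method = "spearman" if montage else "pearson"

    @property
    def channel_mask(self) -> np.ndarray:
        """Channels unmasked in every participating cohort."""
        mask = self.cohort_a.channel_mask.copy()
        if self.cohort_b is not None:
            mask &= self.cohort_b.channel_mask
        return mask


@dataclass
class CorrelationSet:
    """Fisher-z correlations per channel: one row per subject (or pair)."""

    z: np.ndarray  # (n_entries, n_channels)
    entry_ids: list[Any]
    channel_mask: np.ndarray
    method: str
    level: str
    band: str
    meta: dict = field(default_factory=dict)

    @property
    def n_entries(self) -> int:
        return self.z.shape[0]

    @property
    def n_channels(self) -> int:
        return self.z.shape[1]


@dataclass
class GrandAverage:
    """Per-channel grand-averaged correlation (Fisher-z and back-transformed)."""

    z: np.ndarray
    channel_mask: np.ndarray

    @property
    def r(self) -> np.ndarray:
        return np.tanh(self.z)

    @property
    def r_max(self) -> float:
        return float(np.nanmax(np.abs(self.r[self.channel_mask])))


def _mask_from_entries(z: np.ndarray, base_mask: np.ndarray) -> np.ndarray:
    return base_mask & np.all(np.isfinite(z), axis=0)


def within_subject_set(spec: ComparisonSpec) -> CorrelationSet:
    """One entry per subject per channel: corr(viewing 1, viewing 2)."""
    env = spec.cohort_a
    rows, ids = [], []
    for s in env.subjects:
        viewings = env.viewings(spec.band, s)
        if len(viewings) < 2:
            warnings.warn(f"subject {s!r} lacks a viewing; skipped", RuntimeWarning, stacklevel=2)
            continue
        r = channel_correlations(
            env.get(spec.band, s, viewings[0]), env.get(spec.band, s, viewings[1]), spec.method
        )
        rows.append(fisher_z(r))
        ids.append(s)
    z = np.asarray(rows)
    return CorrelationSet(
        z=z,
        entry_ids=ids,
        channel_mask=_mask_from_entries(z, spec.channel_mask),
        method=spec.method,
        level="within_subject",
        band=spec.band,
    )


def _pair_directions(pairing: str) -> list[tuple[int, int]]:
    # (viewing of side A, viewing of side B) index pairs
    if pairing == "cross_viewing":
        return [(0, 1), (1, 0)]
    return [(0, 0), (1, 1)]


def between_subject_set(spec: ComparisonSpec) -> CorrelationSet:
    """Bidirectional pairwise correlations of each subject against the rest
    of the cohort, averaged to one Fisher-z entry per subject."""
    env = spec.cohort_a
    subjects = env.subjects
    if len(subjects) < 2:
        raise ValueError("between_subject comparison needs >= 2 subjects")
    dirs = _pair_directions(spec.pairing)
    rows = []
    for i, si in enumerate(subjects):
        vi = env.viewings(spec.band, si)
        zs = []
        for sj in subjects:
            if sj == si:
                continue
            vj = env.viewings(spec.band, sj)
            for va, vb in dirs:
                r = channel_correlations(
                    env.get(spec.band, si, vi[va]), env.get(spec.band, sj, vj[vb]), spec.method
                )
                zs.append(fisher_z(r))
        rows.append(np.mean(zs, axis=0))
    z = np.asarray(rows)
    return CorrelationSet(
        z=z,
        entry_ids=list(subjects),
        channel_mask=_mask_from_entries(z, spec.channel_mask),
        method=spec.method,
        level="between_subject",
        band=spec.band,
        meta={"pairing": spec.pairing, "n_pairs_per_entry": len(dirs) * (len(subjects) - 1)},
    )


def between_method_set(spec: ComparisonSpec) -> CorrelationSet:
    """All (subject i, viewing) x (subject j, alternate viewing) Fisher-z
    correlations between two cohorts on a shared channel support.

    With ``two_stage_average`` the entries are first averaged per cohort-a
    subject (the flat average over all pairs is the default)."""
    env_a, env_b = spec.cohort_a, spec.cohort_b
    assert env_b is not None
    if env_a.geometry.n_channels != env_b.geometry.n_channels:
        raise ValueError("cohorts must share a channel support")
    band_b = spec.band if spec.band in {k[0] for k in env_b.envelopes} else None
    if band_b is None:
        # hemodynamic cohorts carry a single band-agnostic series
        bands_b = {k[0] for k in env_b.envelopes}
        if len(bands_b) != 1:
            raise ValueError(f"band {spec.band!r} absent from cohort B")
        band_b = next(iter(bands_b))
    dirs = _pair_directions(spec.pairing)
    rows, ids = [], []
    for si in env_a.subjects:
        vi = env_a.viewings(spec.band, si)
        for sj in env_b.subjects:
            vj = env_b.viewings(band_b, sj)
            for va, vb in dirs:
                r = channel_correlations(
                    env_a.get(spec.band, si, vi[va]),
                    env_b.get(band_b, sj, vj[vb]),
                    spec.method,
                )
                rows.append(fisher_z(r))
                ids.append((si, sj, vi[va]))
    z = np.asarray(rows)
    if spec.two_stage_average:
        per_subject = []
        for si in env_a.subjects:
            idx = [k for k, eid in enumerate(ids) if eid[0] == si]
            per_subject.append(z[idx].mean(axis=0))
        z = np.asarray(per_subject)
        ids = list(env_a.subjects)
    return CorrelationSet(
        z=z,
        entry_ids=ids,
        channel_mask=_mask_from_entries(z, spec.channel_mask),
        method=spec.method,
        level="between_method",
        band=spec.band,
        meta={"pairing": spec.pairing, "two_stage": spec.two_stage_average},
    )


def compute_comparison(spec: ComparisonSpec) -> CorrelationSet:
    """Dispatch on ``spec.level``."""
    return {
        "within_subject": within_subject_set,
        "between_subject": between_subject_set,
        "between_method": between_method_set,
    }[spec.level](spec)


def grand_average(cs: CorrelationSet) -> GrandAverage:
    """Mean Fisher-z across entries per channel."""
    if cs.n_entries == 0:
        raise ValueError("empty correlation set")
    return GrandAverage(z=cs.z.mean(axis=0), channel_mask=cs.channel_mask.copy())


def temporal_resolution_sensitivity(
    env: EnvelopeSet,
    band: str,
    rates: list[float],
    grand_average_series: bool = False,
    method: str = "pearson",
) -> pd.DataFrame:
    """Within-subject correlation as a function of sampling rate.

    Each envelope series is linearly interpolated down to every rate in
    ``rates`` (must not exceed the native rate) and the within-subject
    correlation recomputed.  With ``grand_average_series`` the time series
    are first averaged across subjects per viewing, yielding a single
    correlation per channel.  Returns a table with one row per rate:
    mean r over channels (and subjects), and the maximum |r|.
    """
    records = []
    for rate in rates:
        if rate > env.fs + 1e-9:
            raise ValueError(f"rate {rate} Hz exceeds native {env.fs} Hz")

        def at_rate(arr: np.ndarray) -> np.ndarray:
            if np.isclose(rate, env.fs):
                return arr
            rec = resample(Recording(arr, fs=env.fs), rate, method="linear")
            return rec.data

        mask = env.channel_mask
        if grand_average_series:
            v1 = np.mean([at_rate(env.get(band, s, env.viewings(band, s)[0])) for s in env.subjects], axis=0)
            v2 = np.mean([at_rate(env.get(band, s, env.viewings(band, s)[1])) for s in env.subjects], axis=0)
            rs = channel_correlations(v1, v2, method)[None, :]
        else:
            rs = np.asarray(
                [
                    channel_correlations(
                        at_rate(env.get(band, s, env.viewings(band, s)[0])),
                        at_rate(env.get(band, s, env.viewings(band, s)[1])),
                        method,
                    )
                    for s in env.subjects
                ]
            )
        rs = rs[:, mask]
        records.append(
            {
                "rate_hz": rate,
                "band": band,
                "mean_r": float(np.nanmean(rs)),
                "r_max": float(np.nanmax(np.abs(rs))),
                "grand_average_series": grand_average_series,
                "n_samples": at_rate(
                    env.get(band, env.subjects[0], env.viewings(band, env.subjects[0])[0])
                ).shape[1],
            }
        )
    return pd.DataFrame.from_records(records)
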