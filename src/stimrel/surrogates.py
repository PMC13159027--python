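"""iAAFT surrogates, bootstrapped grand-average nulls, and FDR-corrected maps.

Statistical significance of a grand-averaged (GA) correlation is judged
against a null distribution built from iAAFT surrogates: every time series
entering a comparison receives a set of surrogates that preserve its value
distribution exactly and its amplitude spectrum approximately while
randomizing phase structure.  For each comparison entry the designated
side is replaced by a surrogate and the correlation recomputed; GA null
draws are then bootstrapped by sampling one surrogate correlation per
entry and averaging, exactly mirroring the empirical grand average.
Empirical GA values are standardized against the per-channel null
(z = (r - mu_surr) / sigma_surr) and tested with an add-one permutation
p-value, Benjamini-Hochberg corrected across channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from statsmodels.stats.multitest import multipletests

from .containers import stable_stream
from .reliability import (
    ComparisonSpec,
    GrandAverage,
    _pair_directions,
    fisher_z,
)

__all__ = [
    "iaaft_surrogate",
    "iaaft_surrogates_batch",
    "SurrogateStore",
    "surrogate_correlations",
    "NullDistribution",
    "bootstrap_null",
    "null_from_surrogates",
    "ReliabilityMap",
    "standardize_and_test",
]


def _iaaft_core(x: np.ndarray, rng: np.random.Generator, max_iter: int) -> np.ndarray:
    """Vectorized iAAFT on a (channels, T) block, each row independent.

    Iterates spectrum substitution and rank remapping; stops when the rank
    ordering of every row is unchanged between iterations or at
    ``max_iter``.  The iteration runs in single precision (only the value
    ordering matters); the returned surrogate is assembled from the
    double-precision sorted originals, so sorted values match the input
    exactly.
    """
    from scipy import fft as sfft

    C, T = x.shape
    sorted_x = np.sort(x, axis=1)
    sorted_x32 = sorted_x.astype(np.float32)
    target_amp = np.abs(sfft.rfft(x.astype(np.float32), axis=1))
    s = rng.permuted(sorted_x32, axis=1)
    buf = np.empty_like(s)
    order = None
    for _ in range(max_iter):
        spec = sfft.rfft(s, axis=1)
        mag = np.abs(spec)
        np.maximum(mag, np.float32(1e-30), out=mag)
        np.divide(target_amp, mag, out=mag)
        spec *= mag
        y = sfft.irfft(spec, n=T, axis=1)
        new_order = np.argsort(y, axis=1)
        np.put_along_axis(buf, new_order, sorted_x32, axis=1)
        s, buf = buf, s
        if order is not None and np.array_equal(new_order, order):
            order = new_order
            break
        order = new_order
    out = np.empty_like(x)
    np.put_along_axis(out, order, sorted_x, axis=1)
    return out


def iaaft_surrogate(
    x: np.ndarray, max_iter: int = 100, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One iAAFT surrogate of a 1-D series.

    Guarantees ``sorted(surrogate) == sorted(x)`` exactly; the amplitude
    spectrum matches within a small tolerance after convergence.  A
    constant series is returned unchanged with a warning (its surrogate is
    itself).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("need a 1-D series of length >= 8")
    if np.ptp(x) == 0:
        warnings.warn("constant series: surrogate equals input", RuntimeWarning, stacklevel=2)
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _iaaft_core(x[None, :], rng, max_iter)[0]


def iaaft_surrogates_batch(
    data: np.ndarray, n_surr: int, rng: np.random.Generator, max_iter: int = 100
) -> np.ndarray:
    """``n_surr`` independent surrogates of every row of a (C, T) array.

    Returns an (n_surr, C, T) array.  Rows are surrogated jointly per
    draw (vectorized over channels) but independently across draws.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    C, T = data.shape
    out = np.empty((n_surr, C, T))
    # batch draws into one core call, chunked to bound peak memory
    chunk = max(1, int(4096 / max(C, 1)))
    for k0 in range(0, n_surr, chunk):
        k1 = min(k0 + chunk, n_surr)
        tiled = np.tile(data, (k1 - k0, 1))
        out[k0:k1] = _iaaft_core(tiled, rng, max_iter).reshape(k1 - k0, C, T)
    return out


def _corr_batch(x: np.ndarray, surr: np.ndarray, method: str) -> np.ndarray:
    """Per-channel correlations of one (C, T) series block against a
    (K, C, T) stack of surrogates; returns (K, C) on the Fisher-z scale."""
    from scipy.stats import rankdata

    if method == "spearman":
        x = rankdata(x, axis=-1)
        surr = rankdata(surr, axis=-1)
    xc = x - x.mean(axis=-1, keepdims=True)
    sc = surr - surr.mean(axis=-1, keepdims=True)
    xn = np.sqrt(np.einsum("ct,ct->c", xc, xc))
    sn = np.sqrt(np.einsum("kct,kct->kc", sc, sc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ct,kct->kc", xc, sc) / (xn[None, :] * sn)
    np.clip(r, -1.0, 1.0, out=r)
    return fisher_z(r)


@dataclass
class SurrogateStore:
    """Fisher-z surrogate correlations: entries x surrogate index x channel."""

    z: np.ndarray  # (n_entries, n_surr, n_channels)
    entry_ids: list[Any]
    channel_mask: np.ndarray
    replaced_side: str
    seed: int
    level: str
    band: str

    @property
    def n_entries(self) -> int:
        return self.z.shape[0]

    @property
    def n_surr(self) -> int:
        return self.z.shape[1]


def surrogate_correlations(
    spec: ComparisonSpec, n_surr: int = 100, seed: int = 0, max_iter: int = 100
) -> SurrogateStore:
    """Surrogate counterpart of the empirical comparison under ``spec``.

    For every empirical entry, ``n_surr`` Fisher-z correlations are
    computed with the second-listed side of the pair replaced by its iAAFT
    surrogate (for between-method comparisons that is cohort B, i.e. the
    hemodynamic/counterpart side).  Surrogates are generated once per
    (series, viewing) and reused across every entry sharing that series;
    the RNG stream is keyed by (subject, viewing, band) so partial re-runs
    reproduce.
    """
    if n_surr < 2:
        raise ValueError("need at least 2 surrogates")
    env_a = spec.cohort_a
    band = spec.band
    dirs = _pair_directions(spec.pairing)

    def surr_for(env, band_key, subject, viewing) -> np.ndarray:
        rng = stable_stream(seed, "iaaft", env.modality, subject, viewing, band_key)
        return iaaft_surrogates_batch(env.get(band_key, subject, viewing), n_surr, rng, max_iter)

    if spec.level == "within_subject":
        rows, ids = [], []
        for s in env_a.subjects:
            vs = env_a.viewings(band, s)
            if len(vs) < 2:
                continue
            x1 = env_a.get(band, s, vs[0])
            surr2 = surr_for(env_a, band, s, vs[1])
            rows.append(_corr_batch(x1, surr2, spec.method))
            ids.append(s)
        z = np.asarray(rows)
    elif spec.level == "between_subject":
        subjects = env_a.subjects
        C = env_a.geometry.n_channels
        acc = {s: np.zeros((n_surr, C)) for s in subjects}
        n_pairs = {s: 0 for s in subjects}
        # each (subject, viewing) series is surrogated once and its set is
        # consumed against every counterpart entry before moving on, so at
        # most one surrogate stack is held in memory
        for sj in subjects:
            vj = env_a.viewings(band, sj)
            for vbi, vb in enumerate(vj[:2]):
                vai = [va for va, vb_ in dirs if vb_ == vbi]
                surr_set = surr_for(env_a, band, sj, vb)
                for si in subjects:
                    if si == sj:
                        continue
                    vi = env_a.viewings(band, si)
                    for va in vai:
                        acc[si] += _corr_batch(env_a.get(band, si, vi[va]), surr_set, spec.method)
                        n_pairs[si] += 1
        z = np.asarray([acc[s] / n_pairs[s] for s in subjects])
        ids = list(subjects)
    elif spec.level == "between_method":
        env_b = spec.cohort_b
        assert env_b is not None
        bands_b = {k[0] for k in env_b.envelopes}
        band_b = band if band in bands_b else next(iter(bands_b))
        chunks: dict[tuple, np.ndarray] = {}
        for sj in env_b.subjects:
            vj = env_b.viewings(band_b, sj)
            for vbi, vb in enumerate(vj[:2]):
                vai = [va for va, vb_ in dirs if vb_ == vbi]
                surr_set = surr_for(env_b, band_b, sj, vb)
                for si in env_a.subjects:
                    vi = env_a.viewings(band, si)
                    for va in vai:
                        chunks[(si, sj, vi[va])] = _corr_batch(
                            env_a.get(band, si, vi[va]), surr_set, spec.method
                        )
        ids = sorted(chunks)
        z = np.asarray([chunks[k] for k in ids])
    else:  # pragma: no cover
        raise ValueError(spec.level)

    mask = spec.channel_mask & np.all(np.isfinite(z), axis=(0, 1))
    return SurrogateStore(
        z=z,
        entry_ids=ids,
        channel_mask=mask,
        replaced_side="cohort_b" if spec.level == "between_method" else "second_viewing",
        seed=seed,
        level=spec.level,
        band=band,
    )


@dataclass
class NullDistribution:
    """Per-channel bootstrap distribution of GA surrogate correlations."""

    draws: np.ndarray  # (n_draws, n_channels), Fisher-z scale
    channel_mask: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def mu(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def sigma(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=0)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def bootstrap_null(store: SurrogateStore, n_boot: int = 10000, seed: int = 0) -> NullDistribution:
    """Bootstrap GA null draws: each draw samples one surrogate correlation
    per entry (uniformly among the store's surrogates) and averages the
    Fisher-z values across entries, exactly as the empirical grand average
    does."""
    rng = stable_stream(seed, "bootstrap", store.level, store.band)
    E, K, C = store.z.shape
    idx = rng.integers(K, size=(n_boot, E))
    draws = np.zeros((n_boot, C))
    for e in range(E):
        draws += store.z[e, idx[:, e], :]
    draws /= E
    null = NullDistribution(draws=draws, channel_mask=store.channel_mask.copy(), seed=seed)
    if np.all(null.sigma[store.channel_mask] == 0):
        null.meta["degenerate"] = True
    return null


def null_from_surrogates(store: SurrogateStore) -> NullDistribution:
    """Use surrogate correlations directly as the null, without bootstrap.

    This is the single-subject (pooled electrode montage) variant where
    subject-level resampling is impossible: the store must contain exactly
    one entry and its surrogate correlations form the null draws.
    """
    if store.n_entries != 1:
        raise ValueError("direct surrogate null requires a single-entry store")
    return NullDistribution(
        draws=store.z[0].copy(),
        channel_mask=store.channel_mask.copy(),
        seed=store.seed,
        meta={"bootstrap": False},
    )


@dataclass
class ReliabilityMap:
    """Per-channel GA correlation, SNR z-score, p-value, and FDR flag."""

    ga_z: np.ndarray  # Fisher-z scale GA
    z: np.ndarray  # standardized (SNR) score
    p: np.ndarray
    fdr_pass: np.ndarray
    channel_mask: np.ndarray
    q: float
    sided: str
    meta: dict = field(default_factory=dict)

    @property
    def r(self) -> np.ndarray:
        return np.tanh(self.ga_z)

    @property
    def pct_mc(self) -> float:
        """Percentage of unmasked channels surviving FDR correction."""
        n = int(self.channel_mask.sum())
        return 100.0 * int(self.fdr_pass[self.channel_mask].sum()) / n if n else float("nan")


def standardize_and_test(
    ga: GrandAverage,
    null: NullDistribution,
    q: float = 0.05,
    sided: str = "one_sided_positive",
    add_one: bool = True,
) -> ReliabilityMap:
    """Standardize a GA map against its null and apply BH-FDR at level ``q``.

    z = (GA - mu_surr) / sigma_surr per channel.  The p-value is the
    proportion of null GA draws at least as extreme as the empirical GA
    (one-sided positive: draws >= GA; two-sided: |draws| >= |GA|), with
    add-one smoothing (b + 1) / (n + 1) by default.  Channels with a
    degenerate null (sigma = 0) are masked.
    """
    if sided not in ("one_sided_positive", "two_sided"):
        raise ValueError(f"unknown sidedness {sided!r}")
    if ga.z.shape != null.mu.shape:
        raise ValueError("GA and null channel supports differ")
    mask = ga.channel_mask & null.channel_mask
    sigma = null.sigma
    degenerate = sigma <= 1e-12 * np.maximum(1.0, np.abs(null.mu))
    if np.any(degenerate & mask):
        mask = mask & ~degenerate
    z = np.full_like(ga.z, np.nan)
    z[~degenerate] = (ga.z[~degenerate] - null.mu[~degenerate]) / sigma[~degenerate]

    if sided == "one_sided_positive":
        b = (null.draws >= ga.z[None, :]).sum(axis=0)
    else:
        b = (np.abs(null.draws) >= np.abs(ga.z)[None, :]).sum(axis=0)
    n = null.n_draws
    p = (b + 1) / (n + 1) if add_one else b / n
    p = p.astype(float)

    fdr = np.zeros_like(mask)
    if mask.sum():
        reject, _, _, _ = multipletests(p[mask], alpha=q, method="fdr_bh")
        fdr[mask] = reject
    return ReliabilityMap(
        ga_z=ga.z.copy(),
        z=z,
        p=p,
        fdr_pass=fdr,
        channel_mask=mask,
        q=q,
        sided=sided,
    )
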