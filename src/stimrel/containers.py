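"""Core in-memory containers shared by all pipeline stages.

A :class:`Recording` is a channels x samples array with a sampling rate and
identity tags (subject, viewing, modality).  A :class:`ChannelGeometry` holds
millimetre coordinates, labels, and region tags for the channels of one
modality.  An :class:`EnvelopeSet` collects band-limited log-amplitude time
courses for a whole cohort on the common analysis grid (20 Hz, 297 s by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "ChannelGeometry",
    "Recording",
    "EnvelopeSet",
    "ANALYSIS_RATE_HZ",
    "ANALYSIS_DURATION_S",
    "ANALYSIS_SAMPLES",
]

#: Common temporal grid used for every cross-modal comparison.
ANALYSIS_RATE_HZ = 20.0
ANALYSIS_DURATION_S = 297.0
ANALYSIS_SAMPLES = 5940  # 297 s x 20 Hz


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band given by its name and half-power edges in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )

    def validate_for_rate(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_hi} Hz is not below "
                f"the Nyquist frequency {fs / 2} Hz"
            )


#: The canonical band table: seven narrow bands plus a broadband signal.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 28.0),
    BandDefinition("gamma1", 28.0, 46.0),
    BandDefinition("gamma2", 55.0, 70.0),
    BandDefinition("hf", 64.0, 116.0),
    BandDefinition("bb", 0.5, 116.0),
)


def band_table(names: Iterable[str] | None = None) -> tuple[BandDefinition, ...]:
    """Return the default bands, optionally restricted to ``names`` (in order)."""
    if names is None:
        return DEFAULT_BANDS
    by_name = {b.name: b for b in DEFAULT_BANDS}
    try:
        return tuple(by_name[n] for n in names)
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"unknown band name {exc.args[0]!r}") from exc


@dataclass
class ChannelGeometry:
    """Channel coordinates (mm), labels, and region tags for one modality.

    ``kind`` distinguishes regular source grids (``grid``), electrode
    montages (``montage``), and volumetric voxel supports (``voxel``).
    Regular grids expose their spacing in mm.
    """

    coords: np.ndarray  # (n, 3) mm
    labels: list[str]
    region_tags: list[str]
    kind: str = "grid"
    spacing_mm: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array of mm positions")
        if self.coords.shape[0] < 1:
            raise ValueError("geometry needs at least one channel")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("geometry coordinates must be finite")
        if self.kind not in ("grid", "montage", "voxel"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if len(self.labels) != self.n_channels or len(self.region_tags) != self.n_channels:
            raise ValueError("labels/region_tags length must match coords")

    @property
    def n_channels(self) -> int:
        return self.coords.shape[0]

    def mask_for_tag(self, tag: str) -> np.ndarray:
        """Boolean mask of channels whose region tag equals ``tag``."""
        return np.array([t == tag for t in self.region_tags], dtype=bool)

    def centroid_of_tag(self, tag: str) -> np.ndarray:
        mask = self.mask_for_tag(tag)
        if not mask.any():
            raise ValueError(f"no channels tagged {tag!r}")
        return self.coords[mask].mean(axis=0)


@dataclass
class Recording:
    """A channels x samples time series block with identity metadata."""

    data: np.ndarray
    fs: float
    t0: float = 0.0
    subject_id: Any = None
    viewing_id: int | None = None
    modality: str = "ephys"
    geometry: ChannelGeometry | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray | None = None, **kwargs) -> "Recording":
        """Return a shallow copy with ``data`` and selected fields replaced."""
        out = Recording(
            data=self.data.copy() if data is None else data,
            fs=kwargs.pop("fs", self.fs),
            t0=kwargs.pop("t0", self.t0),
            subject_id=kwargs.pop("subject_id", self.subject_id),
            viewing_id=kwargs.pop("viewing_id", self.viewing_id),
            modality=kwargs.pop("modality", self.modality),
            geometry=kwargs.pop("geometry", self.geometry),
            meta=dict(self.meta, **kwargs.pop("meta", {})),
        )
        if kwargs:
            raise TypeError(f"unknown fields: {sorted(kwargs)}")
        return out


@dataclass
class EnvelopeSet:
    """Aligned per-band log-amplitude series for a cohort.

    ``envelopes`` maps ``(band, subject, viewing)`` to a channels x samples
    array on a shared temporal grid and channel support.  ``channel_mask``
    marks channels valid in every member (missing channels from spatial
    mapping are masked out, never silently zeroed).
    """

    envelopes: dict[tuple[str, Any, int], np.ndarray]
    geometry: ChannelGeometry
    fs: float = ANALYSIS_RATE_HZ
    correlation_method: str = "pearson"
    modality: str = "ephys"
    channel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {arr.shape for arr in self.envelopes.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent member shapes: {shapes}")
        if shapes:
            (shape,) = shapes
            if shape[0] != self.geometry.n_channels:
                raise ValueError("channel count does not match geometry")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.geometry.n_channels, dtype=bool)
        else:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)

    @property
    def bands(self) -> list[str]:
        return sorted({k[0] for k in self.envelopes})

    @property
    def subjects(self) -> list[Any]:
        return sorted({k[1] for k in self.envelopes})

    @property
    def n_samples(self) -> int:
        return next(iter(self.envelopes.values())).shape[1]

    def get(self, band: str, subject: Any, viewing: int) -> np.ndarray:
        return self.envelopes[(band, subject, viewing)]

    def viewings(self, band: str, subject: Any) -> list[int]:
        return sorted(v for (b, s, v) in self.envelopes if b == band and s == subject)

    def subset_bands(self, bands: Iterable[str]) -> "EnvelopeSet":
        keep = set(bands)
        return EnvelopeSet(
            envelopes={k: v for k, v in self.envelopes.items() if k[0] in keep},
            geometry=self.geometry,
            fs=self.fs,
            correlation_method=self.correlation_method,
            modality=self.modality,
            channel_mask=self.channel_mask.copy(),
        )


def stable_stream(root_seed: int, *key: Any) -> np.random.Generator:
    """Deterministic per-object RNG stream derived from a root seed.

    Keys (strings or ints) are hashed with CRC32 so that the same logical
    object always receives the same stream regardless of generation order.
    """
    import zlib

    ints = [int(root_seed) & 0x7FFFFFFF]
    for k in key:
        if isinstance(k, (int, np.integer)):
            ints.append(int(k) & 0xFFFFFFFF)
        else:
            ints.append(zlib.crc32(str(k).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(ints)
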