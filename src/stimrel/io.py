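"""Dataset container, geometry tables, and analysis configuration.

A dataset container is a directory holding one ``.npy`` array per
recording, one tab-delimited geometry table per modality
(label, x, y, z, region_tag), the generating configuration, and a JSON
manifest with identity tags and SHA-256 checksums.  Round-trips are
lossless for data, geometry, tags, and masks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .containers import ChannelGeometry, Recording
from .synthetic import CohortDataset, LatentStimulus, SyntheticConfig

__all__ = [
    "AnalysisConfig",
    "geometry_to_tsv",
    "geometry_from_tsv",
    "write_dataset",
    "read_dataset",
]


class IntegrityError(RuntimeError):
    """Container manifest or checksum inconsistency."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def geometry_to_tsv(geom: ChannelGeometry, path: str | Path) -> None:
    path = Path(path)
    lines = ["label\tx\ty\tz\tregion_tag"]
    for lb, (x, y, z), tag in zip(geom.labels, geom.coords, geom.region_tags):
        lines.append(f"{lb}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{tag}")
    path.write_text("\n".join(lines) + "\n")


def geometry_from_tsv(path: str | Path, kind: str = "grid", spacing_mm: float | None = None) -> ChannelGeometry:
    rows = Path(path).read_text().strip().splitlines()[1:]
    labels, coords, tags = [], [], []
    for row in rows:
        lb, x, y, z, tag = row.split("\t")
        labels.append(lb)
        coords.append((float(x), float(y), float(z)))
        tags.append(tag)
    return ChannelGeometry(
        coords=np.asarray(coords), labels=labels, region_tags=tags, kind=kind, spacing_mm=spacing_mm
    )


def write_dataset(cohorts: dict[str, CohortDataset], path: str | Path) -> None:
    """Write one or more modality cohorts into a container directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"recordings": [], "geometry": {}, "latent": {}, "config": "config.yaml"}
    any_ds = next(iter(cohorts.values()))
    (path / "config.yaml").write_text(
        yaml.safe_dump(_config_to_dict(any_ds.truth), sort_keys=True)
    )
    geom_kinds: dict[str, str] = {}
    for modality, ds in cohorts.items():
        geom = ds.geometry[modality]
        fname = f"geometry_{modality}.tsv"
        geometry_to_tsv(geom, path / fname)
        manifest["geometry"][modality] = {
            "file": fname,
            "kind": geom.kind,
            "spacing_mm": geom.spacing_mm,
            "sha256": _sha256(path / fname),
        }
        geom_kinds[modality] = geom.kind
        for i, rec in enumerate(ds.recordings):
            fname = f"{modality}_{rec.subject_id}_{rec.viewing_id}_{rec.meta.get('band') or 'raw'}.npy"
            np.save(path / fname, rec.data)
            manifest["recordings"].append(
                {
                    "file": fname,
                    "modality": modality,
                    "subject": rec.subject_id,
                    "viewing": rec.viewing_id,
                    "band": rec.meta.get("band"),
                    "fs": rec.fs,
                    "t0": rec.t0,
                    "sha256": _sha256(path / fname),
                }
            )
    latent = any_ds.latent
    for name, arr in (
        ("shared", latent.shared),
        ("drive", latent.drive),
        ("audio_envelope", latent.audio_envelope),
    ):
        np.save(path / f"latent_{name}.npy", arr)
        manifest["latent"][name] = {"file": f"latent_{name}.npy", "sha256": _sha256(path / f"latent_{name}.npy")}
    manifest["latent"]["band_names"] = list(latent.band_names)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def _config_to_dict(cfg: SyntheticConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["grid_shape"] = list(d["grid_shape"])
    d["bands"] = list(d["bands"])
    return d


def _config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    d["grid_shape"] = tuple(d["grid_shape"])
    d["bands"] = tuple(d["bands"])
    return SyntheticConfig(**d)


def read_dataset(path: str | Path) -> dict[str, CohortDataset]:
    """Read a container directory back into modality cohorts, verifying
    checksums."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise IntegrityError(f"missing manifest in {path}")
    manifest = json.loads(mpath.read_text())
    truth = _config_from_dict(yaml.safe_load((path / manifest["config"]).read_text()))

    geoms: dict[str, ChannelGeometry] = {}
    for modality, entry in manifest["geometry"].items():
        f = path / entry["file"]
        if not f.exists():
            raise IntegrityError(f"missing geometry file {entry['file']}")
        if _sha256(f) != entry["sha256"]:
            raise IntegrityError(f"checksum mismatch for {entry['file']}")
        geoms[modality] = geometry_from_tsv(f, kind=entry["kind"], spacing_mm=entry["spacing_mm"])

    def load_array(entry: dict) -> np.ndarray:
        f = path / entry["file"]
        if not f.exists():
            raise IntegrityError(f"missing array file {entry['file']}")
        if _sha256(f) != entry["sha256"]:
            raise IntegrityError(f"checksum mismatch for {entry['file']}")
        return np.load(f)

    lat = manifest["latent"]
    latent = LatentStimulus(
        shared=load_array(lat["shared"]),
        drive=load_array(lat["drive"]),
        audio_envelope=load_array(lat["audio_envelope"]),
        band_names=tuple(lat["band_names"]),
        grid_geometry=geoms.get("ephys") or geoms.get("hemo") or next(iter(geoms.values())),
    )

    by_modality: dict[str, list[Recording]] = {}
    for entry in manifest["recordings"]:
        modality = entry["modality"]
        geom = geoms[modality]
        rec = Recording(
            data=load_array(entry),
            fs=entry["fs"],
            t0=entry["t0"],
            subject_id=entry["subject"],
            viewing_id=entry["viewing"],
            modality=modality,
            geometry=geom,
            meta={"band": entry["band"]},
        )
        by_modality.setdefault(modality, []).append(rec)

    out = {}
    for modality, recs in by_modality.items():
        out[modality] = CohortDataset(
            recordings=recs,
            geometry={modality: geoms[modality]},
            latent=latent,
            truth=truth,
            modality=modality,
        )
    return out


@dataclasses.dataclass
class AnalysisConfig:
    """Pipeline settings; the defaults are the canonical analysis settings
    (100 surrogates, 10,000 bootstrap averages, 10,000 surrogate SNR maps,
    q = .05 map-wise and q = .025 cluster-wise, 20 Hz / 297 s grid, 6 mm
    pooling radius, 20 nearest channels for lag estimation)."""

    bands: list[str] = dataclasses.field(
        default_factory=lambda: ["delta", "theta", "alpha", "beta", "gamma1", "gamma2", "hf", "bb"]
    )
    window_duration_s: float = 297.0
    window_start_s: float = 16.74
    analysis_rate_hz: float = 20.0
    max_lag_s: float = 15.0
    n_nearest: int = 20
    radius_mm: float = 6.0
    notch_freqs: list[float] = dataclasses.field(default_factory=list)
    n_surr: int = 100
    n_surr_single_subject: int = 1000
    surrogate_max_iter: int = 10  # spectrum error plateaus within a few iterations
    n_boot: int = 10000
    n_maps: int = 10000
    q_map: float = 0.05
    q_cluster: float = 0.025
    pairing: str = "cross_viewing"
    seed: int = 0
    comparisons: list[dict] = dataclasses.field(
        default_factory=lambda: [
            {"name": "within_ephys", "level": "within_subject", "cohort_a": "ephys",
             "sided": "one_sided_positive"},
            {"name": "between_ephys", "level": "between_subject", "cohort_a": "ephys",
             "sided": "one_sided_positive"},
            {"name": "ephys_vs_hemo", "level": "between_method", "cohort_a": "ephys",
             "cohort_b": "hemo", "sided": "two_sided"},
        ]
    )
    contrasts: list[dict] = dataclasses.field(
        default_factory=lambda: [
            {"name": "between_minus_within", "map_a": "within_ephys",
             "map_b": "between_ephys", "abs_b": False},
            {"name": "crossmodal_minus_between", "map_a": "between_ephys",
             "map_b": "ephys_vs_hemo", "abs_b": True},
        ]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
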