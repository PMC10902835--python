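"""File formats, configuration and run manifests.

Plain-text artifacts only: extended-XYZ trajectories (comment line carries a
``Lattice="…"`` box and a ``cavity="…"`` center), TSV tables with
shortest-round-trip float formatting (so write→read→write is byte
identical), JSON metadata, and TOML run configuration.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .forcefield import SolventFrame
from .knitting import OccupancyRDFSet
from .mc import OccupancyHistogram
from .wham import PnDistribution, ln_K_series

__all__ = [
    "write_xyz_frames",
    "read_xyz_frames",
    "write_window",
    "read_window",
    "write_pn",
    "read_pn",
    "write_rdfset",
    "read_rdfset",
    "load_config",
    "RunManifest",
]


def _fmt(x: float) -> str:
    return repr(float(x))


# --- extended XYZ -----------------------------------------------------------


def write_xyz_frames(frames, path: str | Path) -> None:
    """Extended-XYZ trajectory; box and cavity center live in the comment."""
    lines = []
    for frame in frames:
        bx, by, bz = frame.box_lengths
        cx, cy, cz = frame.cavity_center
        lines.append(str(frame.n_particles))
        lines.append(
            f'Lattice="{_fmt(bx)} 0.0 0.0 0.0 {_fmt(by)} 0.0 0.0 0.0 {_fmt(bz)}" '
            f'Properties=species:S:1:pos:R:3 cavity="{_fmt(cx)} {_fmt(cy)} {_fmt(cz)}"'
        )
        for p in frame.positions:
            lines.append(f"W {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_frames(path: str | Path) -> list[SolventFrame]:
    text = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        n = int(text[i].strip())
        comment = text[i + 1]
        lattice = _extract_quoted(comment, "Lattice")
        cavity = _extract_quoted(comment, "cavity")
        mat = np.array([float(v) for v in lattice.split()]).reshape(3, 3)
        box = np.diag(mat)
        center = np.array([float(v) for v in cavity.split()])
        pos = np.empty((n, 3))
        for k in range(n):
            parts = text[i + 2 + k].split()
            pos[k] = [float(v) for v in parts[1:4]]
        frames.append(SolventFrame(pos, box, center))
        i += 2 + n
    return frames


def _extract_quoted(comment: str, key: str) -> str:
    marker = key + '="'
    start = comment.index(marker) + len(marker)
    return comment[start : comment.index('"', start)]


# --- umbrella window --------------------------------------------------------


def write_window(result, out_dir: str | Path, label: str) -> None:
    """Window sidecar TSV (pass, n, volume, energy) plus JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["pass\tn\tvolume\tenergy"]
    for rec in result.records:
        rows.append(
            f"{int(rec['pass'])}\t{int(rec['n'])}\t{_fmt(rec['volume'])}\t{_fmt(rec['energy'])}"
        )
    (out / f"{label}.tsv").write_text("\n".join(rows) + "\n")
    meta = {
        "k0": result.histogram.k0,
        "n0": result.histogram.n0,
        "total_samples": result.histogram.total,
        "acceptance": result.acceptance,
    }
    (out / f"{label}.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_window(out_dir: str | Path, label: str):
    """Return (OccupancyHistogram, occupancy time series) for one window."""
    out = Path(out_dir)
    meta = json.loads((out / f"{label}.json").read_text())
    lines = (out / f"{label}.tsv").read_text().splitlines()[1:]
    series = np.array([int(line.split("\t")[1]) for line in lines], dtype=np.int64)
    hist = OccupancyHistogram.from_samples(series, k0=meta["k0"], n0=meta["n0"])
    return hist, series


# --- p_n tables -------------------------------------------------------------


def write_pn(dist: PnDistribution, path: str | Path) -> None:
    rows = ["n\tp_n\tln_p_n\tln_K_n\tstderr"]
    ln_k = ln_K_series(dist.p)
    with np.errstate(divide="ignore"):
        ln_p = np.log(dist.p)
    for n, p in enumerate(dist.p):
        lk = ln_k[n] if n < len(ln_k) else float("nan")
        err = dist.stderr[n] if dist.stderr is not None else float("nan")
        rows.append(f"{n}\t{_fmt(p)}\t{_fmt(ln_p[n])}\t{_fmt(lk)}\t{_fmt(err)}")
    Path(path).write_text("\n".join(rows) + "\n")
    meta_path = Path(path).with_suffix(".json")
    meta_path.write_text(
        json.dumps({"provenance": dist.provenance, **dist.meta}, indent=2,
                   sort_keys=True, default=str) + "\n"
    )


def read_pn(path: str | Path) -> PnDistribution:
    lines = Path(path).read_text().splitlines()[1:]
    p = np.array([float(line.split("\t")[1]) for line in lines])
    err = np.array([float(line.split("\t")[4]) for line in lines])
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    provenance = meta.pop("provenance", "wham")
    return PnDistribution.from_unnormalized(
        p, provenance=provenance, stderr=err if np.isfinite(err).any() else None,
        meta=meta,
    )


# --- occupancy-resolved RDF sets -------------------------------------------


def write_rdfset(gset: OccupancyRDFSet, out_dir: str | Path) -> None:
    """One TSV per occupancy state (r, g, count) plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    states = []
    for n in range(gset.g.shape[0]):
        if np.all(np.isnan(gset.g[n])):
            continue
        rows = ["r\tg\tcount"]
        for r, g, c in zip(gset.r, gset.g[n], gset.counts[n]):
            rows.append(f"{_fmt(r)}\t{_fmt(g)}\t{_fmt(c)}")
        (out / f"g_{n:04d}.tsv").write_text("\n".join(rows) + "\n")
        states.append(n)
    manifest = {
        "R": gset.R,
        "rho": gset.rho,
        "bin_width": gset.bin_width,
        "n_bins": len(gset.r),
        "states": states,
        "frame_counts": {str(n): int(gset.frame_counts[n]) for n in states},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def read_rdfset(out_dir: str | Path) -> OccupancyRDFSet:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    states = manifest["states"]
    n_max = max(states)
    n_bins = manifest["n_bins"]
    r = None
    g = np.full((n_max + 1, n_bins), np.nan)
    counts = np.zeros((n_max + 1, n_bins))
    frame_counts = np.zeros(n_max + 1, dtype=np.int64)
    for n in states:
        lines = (out / f"g_{n:04d}.tsv").read_text().splitlines()[1:]
        cols = np.array([[float(v) for v in line.split("\t")] for line in lines])
        if r is None:
            r = cols[:, 0]
        g[n] = cols[:, 1]
        counts[n] = cols[:, 2]
        frame_counts[n] = manifest["frame_counts"][str(n)]
    return OccupancyRDFSet(
        r=r, g=g, counts=counts, frame_counts=frame_counts,
        R=manifest["R"], rho=manifest["rho"],
    )


# --- configuration ----------------------------------------------------------

_CONFIG_KEYS = {
    "temperature", "pressure", "n_particles", "solvent_model", "seed",
    "passes_equilibration", "passes_production", "volume_move_interval",
    "target_acceptance", "rho_init", "hs_diameter", "cavity_moves_per_pass",
    "frame_interval", "tune_interval",
    # cavity / ladder
    "cavity_radius", "k0", "n0", "delta_n0", "k0_min", "k0_max",
    # theory
    "rho", "kappa_T", "d_ww", "gamma", "delta",
    # misc
    "params_file", "bin_width",
}


def load_config(path: str | Path, overrides: dict | None = None) -> dict:
    """Parse a flat TOML run configuration; unknown keys are errors.

    ``overrides`` (e.g. from CLI flags) replace file values.
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if overrides:
        bad = set(overrides) - _CONFIG_KEYS
        if bad:
            raise ValueError(f"unknown override keys: {sorted(bad)}")
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


# --- run manifest -----------------------------------------------------------


@dataclass
class RunManifest:
    """Traceability record: every output file maps to a manifest entry."""

    seed: int
    config_hash: str
    code_version: str
    stages: dict = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    @classmethod
    def create(cls, config: dict, seed: int) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(
            seed=seed,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            code_version=__version__,
        )

    def add_stage(self, name: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages[name] = {"inputs": inputs, "outputs": outputs}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
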