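"""CSV/FASTA readers and writers and the run-configuration object.

All dialects are plain comma-separated text with a header row and '.'
decimals.  Trace and rate files carry their experimental metadata in
``# key: value`` comment lines above the header; plate files put the
wavelength in the first column and one column per buffer pH, labelled by
the pH value.  Malformed content is reported with line numbers.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from dopadiox.mechanism import KineticTrace, TraceMetadata
from dopadiox.physchem import TitrationDataset
from dopadiox.steady_state import RateDataset

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_plate_csv",
    "write_plate_csv",
    "read_rates_csv",
    "write_rates_csv",
    "read_fasta",
    "RunConfig",
]

_META_FIELDS = {f.name for f in fields(TraceMetadata)}


def _read_commented_csv(path) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    body_lines = []
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                k, v = stripped.split(":", 1)
                meta[k.strip()] = v.strip()
        elif line.strip():
            body_lines.append((i, line))
    if not body_lines:
        raise ValueError(f"{path}: no data rows")
    frame = pd.read_csv(
        _io.StringIO("\n".join(ln for _, ln in body_lines)),
        float_precision="round_trip",
    )
    return meta, frame


def write_trace_csv(trace: KineticTrace, path) -> None:
    lines = [f"# {k}: {v}" for k, v in asdict(trace.metadata).items()]
    lines.append("time_s,absorbance")
    lines += [f"{float(t)!r},{float(a)!r}" for t, a in zip(trace.times, trace.absorbance)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_csv(path) -> KineticTrace:
    meta, frame = _read_commented_csv(path)
    for col in ("time_s", "absorbance"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = frame["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 2
        raise ValueError(f"{path}: non-monotone time column at data row {bad}")
    kwargs = {}
    for name in _META_FIELDS:
        if name in meta:
            kwargs[name] = int(meta[name]) if name == "replicates" else float(meta[name])
    return KineticTrace(t, frame["absorbance"].to_numpy(float), TraceMetadata(**kwargs))


def write_plate_csv(dataset: TitrationDataset, data_path, blank_path) -> None:
    for matrix, path in ((dataset.absorbance, data_path), (dataset.blank, blank_path)):
        frame = pd.DataFrame(
            matrix,
            index=pd.Index(dataset.wavelengths, name="wavelength_nm"),
            columns=[repr(float(p)) for p in dataset.ph_values],
        )
        with open(path, "w") as fh:
            fh.write(f"# compound_concentration_um: {dataset.compound_concentration_um}\n")
            frame.to_csv(fh)


def _read_plate_matrix(path) -> tuple[dict, np.ndarray, np.ndarray, np.ndarray]:
    meta, frame = _read_commented_csv(path)
    if frame.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be 'wavelength_nm'")
    ph_labels = list(frame.columns[1:])
    if len(set(ph_labels)) != len(ph_labels):
        dup = sorted({c for c in ph_labels if ph_labels.count(c) > 1})
        raise ValueError(f"{path}: duplicated pH column(s) {dup}")
    try:
        ph = np.array([float(c) for c in ph_labels])
    except ValueError as exc:
        raise ValueError(f"{path}: pH column labels must be numeric: {exc}") from exc
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path}: ragged matrix near data row {row}")
    return meta, frame["wavelength_nm"].to_numpy(float), ph, frame.iloc[:, 1:].to_numpy(float)


def read_plate_csv(data_path, blank_path) -> TitrationDataset:
    meta, wl, ph, absorbance = _read_plate_matrix(data_path)
    _, wl_b, ph_b, blank = _read_plate_matrix(blank_path)
    if not (np.array_equal(wl, wl_b) and np.array_equal(ph, ph_b)):
        raise ValueError("blank plate axes do not match the data plate")
    st = float(meta.get("compound_concentration_um", 200.0))
    return TitrationDataset(wl, ph, absorbance, blank, st)


def write_rates_csv(data: RateDataset, path) -> None:
    lines = [
        f"# enzyme_uM: {float(data.enzyme_concentration)!r}",
        f"# varied_substrate: {data.varied_substrate}",
        f"# temperature_c: {float(data.temperature_c)!r}",
        "substrate_uM,rate_uM_per_min",
    ]
    lines += [
        f"{float(s)!r},{float(r)!r}" for s, r in zip(data.substrate_concentrations, data.rates)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rates_csv(path) -> RateDataset:
    meta, frame = _read_commented_csv(path)
    for col in ("substrate_uM", "rate_uM_per_min"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return RateDataset(
        frame["substrate_uM"].to_numpy(float),
        frame["rate_uM_per_min"].to_numpy(float),
        enzyme_concentration=float(meta.get("enzyme_uM", 1.0)),
        varied_substrate=meta.get("varied_substrate", "catechol"),
        temperature_c=float(meta.get("temperature_c", 22.0)),
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (id, sequence) pairs, in file order."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Resolved parameters of an analysis run.

    Unknown keys in a config file are rejected; every command writes the
    resolved configuration beside its outputs for reproducibility.
    """

    seed: int = 0
    out_dir: str = "."
    pathlength_cm: float = 1.0
    o2_saturation_um: float = 1300.0
    fit_window: tuple[float, float] = (0.8, 45.0)
    threshold: float = 0.83
    reference_ph: float = 3.0
    titration_mode: str = "total"
    pka: float = 7.51
    ph: float = 7.35
    free_parameters: tuple[str, ...] = ("k6", "k7", "a")
    noise_sd: float = 0.002
    replicate_count: int = 15
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fit_window" in raw:
            raw["fit_window"] = tuple(raw["fit_window"])
        if "free_parameters" in raw:
            raw["free_parameters"] = tuple(raw["free_parameters"])
        return cls(**raw)

    def write_resolved(self, out_dir) -> Path:
        out = Path(out_dir) / "resolved_config.yaml"
        payload = asdict(self)
        payload["fit_window"] = list(self.fit_window)
        payload["free_parameters"] = list(self.free_parameters)
        out.write_text(yaml.safe_dump(payload, sort_keys=True))
        return out


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
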