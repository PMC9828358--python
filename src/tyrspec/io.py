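"""Plain-text readers and writers for the columnar formats used throughout.

Decays/IRFs are two-column CSV (time_ns, counts); titrations are
(concentration, value[, sd]) CSV; dihedral tables are (frame, chi1_deg
[, chi2_deg]) CSV, with the whitespace layout of common trajectory dihedral
tools also accepted; SASA tables carry one value per frame(-residue) row.
Fit results and generator specs are written as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anisotropy import AnisotropyTitration
from .exceptions import ValidationError
from .rotamers import DihedralSeries, SASASamples
from .tcspc import DecayHistogram
from .tension import TensionTitration

__all__ = [
    "write_decay_csv",
    "read_decay_csv",
    "write_anisotropy_csv",
    "read_anisotropy_csv",
    "write_tension_csv",
    "read_tension_csv",
    "write_dihedral_csv",
    "read_dihedral_table",
    "write_sasa_csv",
    "read_sasa_csv",
    "write_json",
    "write_sidecar",
]


def write_decay_csv(path, hist: DecayHistogram) -> None:
    df = pd.DataFrame({"time_ns": hist.times, "counts": hist.counts})
    df.to_csv(path, index=False)


def read_decay_csv(path) -> DecayHistogram:
    df = pd.read_csv(path)
    if not {"time_ns", "counts"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns time_ns,counts")
    t = df["time_ns"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError(f"{path}: need at least two channels")
    widths = np.diff(t)
    if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-6):
        raise ValidationError(f"{path}: time axis must be uniform and increasing")
    counts = df["counts"].to_numpy(dtype=float)
    return DecayHistogram(counts, float(widths[0]), origin_channel=int(np.argmax(counts)))


def write_anisotropy_csv(path, t: AnisotropyTitration) -> None:
    data = {"conc_uM": t.concentration, "anisotropy": t.anisotropy}
    if t.anisotropy_sd is not None:
        data["anisotropy_sd"] = t.anisotropy_sd
    pd.DataFrame(data).to_csv(path, index=False)


def read_anisotropy_csv(path) -> AnisotropyTitration:
    df = pd.read_csv(path)
    if not {"conc_uM", "anisotropy"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns conc_uM,anisotropy[,anisotropy_sd]")
    sd = df["anisotropy_sd"].to_numpy(dtype=float) if "anisotropy_sd" in df else None
    return AnisotropyTitration(
        concentration=df["conc_uM"].to_numpy(dtype=float),
        anisotropy=df["anisotropy"].to_numpy(dtype=float),
        anisotropy_sd=sd,
    )


def write_tension_csv(path, t: TensionTitration) -> None:
    data = {"conc_nM": t.concentration, "gamma_mNm": t.gamma}
    if t.gamma_sd is not None:
        data["gamma_sd"] = t.gamma_sd
    pd.DataFrame(data).to_csv(path, index=False)


def read_tension_csv(path) -> TensionTitration:
    df = pd.read_csv(path)
    if not {"conc_nM", "gamma_mNm"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns conc_nM,gamma_mNm[,gamma_sd]")
    sd = df["gamma_sd"].to_numpy(dtype=float) if "gamma_sd" in df else None
    return TensionTitration(
        concentration=df["conc_nM"].to_numpy(dtype=float),
        gamma=df["gamma_mNm"].to_numpy(dtype=float),
        gamma_sd=sd,
    )


def write_dihedral_csv(path, series: DihedralSeries) -> None:
    data = {"frame": series.frames, "chi1_deg": series.chi1}
    if series.chi2 is not None:
        data["chi2_deg"] = series.chi2
    pd.DataFrame(data).to_csv(path, index=False)


def read_dihedral_table(path) -> DihedralSeries:
    """Read a dihedral table.

    Accepts the native CSV layout (frame, chi1_deg[, chi2_deg]) and the
    headerless whitespace tables produced by common trajectory dihedral
    tools (comment lines starting with '#' or '@' are skipped; the first
    column is the frame/time index, the second chi1, an optional third
    chi2).
    """
    text = Path(path).read_text()
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith(("#", "@"))
    ]
    if not lines:
        raise ValidationError(f"{path}: empty dihedral table")
    first = lines[0]
    if "," in first:
        df = pd.read_csv(path, comment="#")
        if "chi1_deg" not in df.columns:
            raise ValidationError(f"{path}: expected a chi1_deg column")
        chi2 = df["chi2_deg"].to_numpy(dtype=float) if "chi2_deg" in df else None
        return DihedralSeries(
            chi1=df["chi1_deg"].to_numpy(dtype=float),
            chi2=chi2,
            frames=df["frame"].to_numpy() if "frame" in df else None,
        )
    rows = [ln.split() for ln in lines]
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] < 2:
        raise ValidationError(f"{path}: whitespace table needs at least two columns")
    chi2 = arr[:, 2] if arr.shape[1] > 2 else None
    return DihedralSeries(chi1=arr[:, 1], chi2=chi2, frames=arr[:, 0])


def write_sasa_csv(path, samples: SASASamples) -> None:
    pd.DataFrame(
        {"frame": np.arange(samples.n), "sasa_nm2": samples.values}
    ).to_csv(path, index=False)


def read_sasa_csv(path) -> SASASamples:
    df = pd.read_csv(path)
    col = "sasa_nm2" if "sasa_nm2" in df.columns else df.columns[-1]
    return SASASamples(values=df[col].to_numpy(dtype=float))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def write_sidecar(path, spec_dict: dict, seed: int) -> None:
    """JSON sidecar recording the generating spec and seed next to a data
    file."""
    write_json(path, {"spec": spec_dict, "seed": seed})
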