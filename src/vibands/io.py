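"""CSV readers and writers for spectra, pigment tables and extract ODs.

Two spectrum layouts are supported:

* wide — first column ``wavelength_nm``, one column per sample id;
* long — columns ``sample_id``, ``wavelength_nm``, ``value``.

Raw radiance pairs (object / reference panel) use the wide layout with
matching sample columns in both files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import SampleSet, Spectrum

__all__ = [
    "read_spectra_wide", "write_spectra_wide",
    "read_spectra_long", "write_spectra_long",
    "read_pigments", "write_pigments",
    "read_radiance_pair",
    "read_sample_set", "write_sample_set",
]


def read_spectra_wide(path: str | Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError("wide spectra CSV must start with a wavelength_nm column")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    return [Spectrum(wl, df[c].to_numpy(dtype=float), str(c))
            for c in df.columns[1:]]


def write_spectra_wide(spectra: list[Spectrum], path: str | Path) -> None:
    if not spectra:
        raise ValueError("nothing to write")
    wl = spectra[0].wavelengths
    data = {"wavelength_nm": wl}
    for s in spectra:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("all spectra must share one wavelength grid")
        data[s.sample_id or f"s{len(data)}"] = s.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_spectra_long(path: str | Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    required = {"sample_id", "wavelength_nm", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"long spectra CSV needs columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("wavelength_nm")
        out.append(Spectrum(grp["wavelength_nm"].to_numpy(dtype=float),
                            grp["value"].to_numpy(dtype=float), str(sid)))
    return out


def write_spectra_long(spectra: list[Spectrum], path: str | Path) -> None:
    frames = [pd.DataFrame({"sample_id": s.sample_id,
                            "wavelength_nm": s.wavelengths,
                            "value": s.values}) for s in spectra]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pigments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "chl_mg_per_l", "car_mg_per_l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pigment CSV missing columns: {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_pigments(pigments: pd.DataFrame, path: str | Path) -> None:
    pigments.to_csv(path, index=False)


def read_radiance_pair(obj_path: str | Path, ref_path: str | Path,
                       ) -> list[tuple[Spectrum, Spectrum]]:
    """Read matched object/reference radiance files (wide layout).

    Returns one (object, reference) pair per shared sample column; the
    reference file may alternatively hold a single shared panel column.
    """
    obj = read_spectra_wide(obj_path)
    ref = read_spectra_wide(ref_path)
    if len(ref) == 1:
        return [(o, ref[0].copy_with(ref[0].values, o.sample_id)) for o in obj]
    ref_by_id = {r.sample_id: r for r in ref}
    pairs = []
    for o in obj:
        if o.sample_id not in ref_by_id:
            raise ValueError(f"no reference radiance for sample {o.sample_id!r}")
        pairs.append((o, ref_by_id[o.sample_id]))
    return pairs


def read_sample_set(spectra_path: str | Path, pigments_path: str | Path) -> SampleSet:
    """Load a calibration set, aligning pigment rows to spectrum columns."""
    spectra = read_spectra_wide(spectra_path)
    pigments = read_pigments(pigments_path)
    order = {sid: i for i, sid in enumerate(pigments["sample_id"])}
    missing = [s.sample_id for s in spectra if s.sample_id not in order]
    if missing:
        raise ValueError(f"samples without pigment ground truth: {missing}")
    spectra.sort(key=lambda s: order[s.sample_id])
    keep = pigments[pigments["sample_id"].isin({s.sample_id for s in spectra})]
    return SampleSet.from_spectra(spectra, keep)


def write_sample_set(samples: SampleSet, out_dir: str | Path,
                     ods: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write spectra.csv / pigments.csv (and optionally ods.csv) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"spectra": out_dir / "spectra.csv",
             "pigments": out_dir / "pigments.csv"}
    write_spectra_wide(samples.spectra(), paths["spectra"])
    write_pigments(samples.pigments, paths["pigments"])
    if ods is not None:
        paths["ods"] = out_dir / "ods.csv"
        ods.to_csv(paths["ods"], index=False)
    return paths
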