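"""Reference photophysics tables shipped with the package.

The four tables (1P photophysics, 2P observables, dipole/field components,
TICT parameters) and the vacuum-chromophore constants are stored exactly
as published — including the separate uncertainty columns — so rounding
provenance is preserved.  Derived quantities (kR, kNR, γ, fields) are
always recomputed by the analysis modules, never trusted from the files;
the printed rate columns are retained only for a per-row cross-check.

Files are pinned by SHA-256; loading refuses modified data.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .fieldsolver import VacuumChromophore
from .marcus import MarcusConstants, MarcusParameters
from .photophysics import PhotophysicsRecord, decay_rates

__all__ = [
    "ReferenceTables",
    "load_fixtures",
    "export_fixtures",
    "marcus_fit_inputs",
    "MARCUS_FIT_INCLUDE",
    "RATE_CROSSCHECK_TOL_NS",
]

_CHECKSUMS = {
    "table1.csv": "2d3ae2b24553bcac1b9bbbb44576860252ceee5f0eef962f6b0a3ddfa698edd4",
    "table2.csv": "b2cd4ec3d1d7d28b389af9c34c54c906029a920d150d1b159d7f9d6d5bfb91f0",
    "table3.csv": "63d02fa7107e4107a418394b32b21e490c05a4537bb81bdf171529b8c6f8df91",
    "table4.json": "2c8a5445c4a6bfd32ec93d81a7dfe9589265e41920f8d79ca4ebc9371029f908",
    "vacuum.json": "964a3c0e699d77ee318ed9a8f60961fe988b263eea6734ddfaedcb3695958c13",
}

# Proteins entering the Marcus quadratic fit.  mScarlet (sterically locked
# phenolate pocket) and eqFP670 (excited-state conformer inaccessible to
# ground-state 2PA) are excluded on mechanistic grounds; the exclusion is
# an explicit list, never automatic.
MARCUS_FIT_INCLUDE = (
    "DsRed2",
    "mCherry pH 11.4",
    "mCherry pH 7.4",
    "XRFP (red-shifted)",
    "mPlum (red-shifted)",
)

RATE_CROSSCHECK_TOL_NS = 0.004


@dataclass(frozen=True)
class ReferenceTables:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: dict
    vacuum: VacuumChromophore
    records: tuple[PhotophysicsRecord, ...]

    @property
    def marcus_constants(self) -> MarcusConstants:
        return MarcusConstants(q=self.table4["q_esu"],
                               dG_vac=self.table4["dG_vac_kcal_mol"])

    @property
    def marcus_parameters(self) -> MarcusParameters:
        t4 = self.table4
        return MarcusParameters(
            lambda_reorg=t4["lambda_kcal_mol"],
            dx=t4["dx_A"],
            dy=t4["dy_A"],
            B=t4["B_s"],
            eta=t4["eta"],
        )


def _data_path(name: str) -> Path:
    return Path(resources.files("rfpfield") / "data" / name)


def _read_verified(name: str) -> bytes:
    raw = _data_path(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name} checksum mismatch: got {digest}, "
            f"expected {_CHECKSUMS[name]}; refusing to load modified data"
        )
    return raw


def load_fixtures(verify: bool = True) -> ReferenceTables:
    """Load the reference tables as typed, validated objects.

    With ``verify`` (default) the file checksums are enforced and the
    kR/kNR derived from (φ, τ) are cross-checked against the printed
    columns to within 0.004 ns⁻¹ per row.
    """
    reader = _read_verified if verify else lambda n: _data_path(n).read_bytes()
    import io

    t1 = pd.read_csv(io.BytesIO(reader("table1.csv")))
    t2 = pd.read_csv(io.BytesIO(reader("table2.csv")))
    t3 = pd.read_csv(io.BytesIO(reader("table3.csv")))
    t4 = json.loads(reader("table4.json"))
    vac = json.loads(reader("vacuum.json"))

    records = tuple(
        PhotophysicsRecord(
            name=row["name"],
            lambda_abs=row["lambda_abs_nm"],
            eps_max=row["eps_max"],
            lambda_fl=row["lambda_fl_nm"],
            phi=row["phi"],
            tau=row["tau_ns"],
        )
        for _, row in t1.iterrows()
    )
    if verify:
        for rec, (_, row) in zip(records, t1.iterrows()):
            kr, knr = decay_rates(row["phi"], row["tau_ns"])
            if abs(kr - row["kR_printed_ns"]) > RATE_CROSSCHECK_TOL_NS:
                raise RuntimeError(
                    f"{rec.name}: recomputed kR {kr:.4f} ns^-1 deviates from "
                    f"printed {row['kR_printed_ns']}"
                )
            if abs(knr - row["kNR_printed_ns"]) > max(
                RATE_CROSSCHECK_TOL_NS, 0.01 * row["kNR_printed_ns"]
            ):
                raise RuntimeError(
                    f"{rec.name}: recomputed kNR {knr:.4f} ns^-1 deviates from "
                    f"printed {row['kNR_printed_ns']}"
                )

    vacuum = VacuumChromophore(
        dmu0_x=vac["dmu0_x_D"],
        dmu0_y=vac["dmu0_y_D"],
        dalpha_xx=vac["dalpha_xx_A3"],
        dalpha_yy=vac["dalpha_yy_A3"],
        nu0=vac["nu0_cm"],
    )
    return ReferenceTables(table1=t1, table2=t2, table3=t3, table4=t4,
                           vacuum=vacuum, records=records)


def _base_protein(label: str) -> str:
    """Map a per-form label like 'XRFP (red-shifted)' to its protein name."""
    if label.startswith("mCherry pH"):
        return label
    return label.split(" (")[0]


def marcus_fit_inputs(
    fixtures: ReferenceTables,
    include: tuple[str, ...] = MARCUS_FIT_INCLUDE,
) -> list[tuple[float, float, float]]:
    """(kNR ns⁻¹, Ex, Ey) triples for the Marcus fit, joined across tables.

    kNR comes from (φ, τ) of the 1P table for the parent protein; the
    fields come from the dipole/field table rows named in ``include``.
    """
    knr_by_protein = {r.name: r.kNR for r in fixtures.records}
    t3 = fixtures.table3.set_index("name")
    out = []
    missing = []
    for label in include:
        if label not in t3.index or _base_protein(label) not in knr_by_protein:
            missing.append(label)
            continue
        row = t3.loc[label]
        out.append((knr_by_protein[_base_protein(label)],
                    float(row["ex_mvcm"]), float(row["ey_mvcm"])))
    if missing:
        raise KeyError(f"labels not found across tables: {missing}")
    return out


def export_fixtures(directory) -> list[Path]:
    """Copy the pinned fixture files into ``directory`` for inspection."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _CHECKSUMS:
        _read_verified(name)
        dest = directory / name
        shutil.copyfile(_data_path(name), dest)
        written.append(dest)
    return written
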