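"""Readers/writers for NP tables, configs, time series and model stores.

File formats are deliberately plain: UTF-8 CSV/TSV with a header row for
tabular data, YAML for the cell/medium/physics configuration, JSON for the
fitted per-cell-line model store.  SMILES strings are carried as opaque
labels.  Validation follows the dataset rules: unique NP ids per cell line,
and no mixing of hydrodynamic- and TEM-sized particles within one
regression group (sizes measured in solution include the solvation shell
and are not comparable with dry TEM core sizes).
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .arrhenius import CellLineModel
from .materials import WATER, MediumSpec, SurfaceChemistry
from .xdlvo import VesicleRule, XdlvoParameters

__all__ = [
    "SizeType",
    "NanoparticleSpec",
    "Dataset",
    "SchemaError",
    "GENERIC_CELL",
    "read_np_table",
    "write_np_table",
    "load_fixtures",
    "read_cell_config",
    "read_time_series",
    "save_models",
    "load_models",
]

#: Generic cell-surface chemistry: gamma_lw 39, gamma_plus 2.6, gamma_minus 71
#: mJ/m^2 (derived gamma_ab ~ 27) and surface potential -40 mV, applied to
#: cell membranes and transport vesicles alike.
GENERIC_CELL = SurfaceChemistry(
    "generic_cell", gamma_lw=39.0, gamma_plus=2.6, gamma_minus=71.0, psi0=-40.0
)

REQUIRED_COLUMNS = [
    "np_id",
    "coating",
    "diameter_nm",
    "size_type",
    "gamma_lw",
    "gamma_plus",
    "gamma_minus",
    "psi0_mv",
    "cell_line",
]
OPTIONAL_COLUMNS = ["smiles", "log_kow", "k_exo_per_s"]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


class SizeType(str, enum.Enum):
    HYDRODYNAMIC = "hydrodynamic"
    TEM = "tem"


@dataclass(frozen=True)
class NanoparticleSpec:
    """One coated NP as seen by one cell line."""

    np_id: str
    coating: str
    diameter_nm: float
    size_type: SizeType
    chemistry: SurfaceChemistry
    cell_line: str
    smiles: str | None = None
    log_kow: float | None = None
    k_exo_per_s: float | None = None

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter_nm}")

    @property
    def radius_nm(self) -> float:
        return self.diameter_nm / 2.0


@dataclass
class Dataset:
    """A validated NP panel plus any attached rate records and warnings."""

    nanoparticles: list[NanoparticleSpec]
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nanoparticles)

    def by_cell_line(self, cell_line: str) -> list[NanoparticleSpec]:
        return [np_ for np_ in self.nanoparticles if np_.cell_line == cell_line]


def _validate(nps: list[NanoparticleSpec]) -> list[str]:
    warnings_: list[str] = []
    seen: dict[tuple[str, str], None] = {}
    for np_ in nps:
        key = (np_.cell_line, np_.np_id)
        if key in seen:
            raise SchemaError(f"duplicate np_id {np_.np_id!r} for cell line {np_.cell_line!r}")
        seen[key] = None
        for comp in ("gamma_lw", "gamma_plus", "gamma_minus"):
            v = getattr(np_.chemistry, comp)
            if not 0 <= v <= 100:
                warnings_.append(
                    f"{np_.np_id}: {comp}={v} mJ/m^2 outside plausible 0-100 range"
                )
    groups: dict[str, set[SizeType]] = {}
    for np_ in nps:
        groups.setdefault(np_.cell_line, set()).add(np_.size_type)
    for cell, kinds in sorted(groups.items()):
        if len(kinds) > 1:
            warnings_.append(
                f"cell line {cell!r} mixes hydrodynamic and TEM sizes; these must "
                "not enter the same regression"
            )
    return warnings_


def read_np_table(path: str | Path) -> Dataset:
    """Read a nanoparticle property table (CSV, or TSV by extension).

    Required columns: np_id, coating, diameter_nm, size_type, gamma_lw,
    gamma_plus, gamma_minus, psi0_mv, cell_line.  Optional: smiles, log_kow,
    k_exo_per_s.  Mixing size-measurement types within one cell line is
    allowed at read time but attaches a warning (it invalidates a joint
    regression).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")

    for col in ("diameter_nm", "gamma_lw", "gamma_plus", "gamma_minus", "psi0_mv"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based, plus header
            raise SchemaError(f"non-numeric value in column {col!r} at line {row}")
        df[col] = pd.to_numeric(df[col])

    nps = []
    for _, row in df.iterrows():
        try:
            size_type = SizeType(str(row["size_type"]).strip().lower())
        except ValueError as exc:
            raise SchemaError(
                f"size_type must be 'hydrodynamic' or 'tem', got {row['size_type']!r}"
            ) from exc
        chem = SurfaceChemistry(
            name=str(row["coating"]),
            gamma_lw=float(row["gamma_lw"]),
            gamma_plus=float(row["gamma_plus"]),
            gamma_minus=float(row["gamma_minus"]),
            psi0=float(row["psi0_mv"]),
        )
        nps.append(
            NanoparticleSpec(
                np_id=str(row["np_id"]),
                coating=str(row["coating"]),
                diameter_nm=float(row["diameter_nm"]),
                size_type=size_type,
                chemistry=chem,
                cell_line=str(row["cell_line"]),
                smiles=str(row["smiles"]) if "smiles" in df.columns and pd.notna(row.get("smiles")) else None,
                log_kow=float(row["log_kow"]) if "log_kow" in df.columns and pd.notna(row.get("log_kow")) else None,
                k_exo_per_s=float(row["k_exo_per_s"]) if "k_exo_per_s" in df.columns and pd.notna(row.get("k_exo_per_s")) else None,
            )
        )
    return Dataset(nanoparticles=nps, provenance=str(path), warnings=_validate(nps))


def write_np_table(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset back to CSV; inverse of :func:`read_np_table`."""
    rows = []
    for np_ in dataset.nanoparticles:
        rows.append(
            {
                "np_id": np_.np_id,
                "coating": np_.coating,
                "diameter_nm": np_.diameter_nm,
                "size_type": np_.size_type.value,
                "gamma_lw": np_.chemistry.gamma_lw,
                "gamma_plus": np_.chemistry.gamma_plus,
                "gamma_minus": np_.chemistry.gamma_minus,
                "psi0_mv": np_.chemistry.psi0,
                "cell_line": np_.cell_line,
                "smiles": np_.smiles,
                "log_kow": np_.log_kow,
                "k_exo_per_s": np_.k_exo_per_s,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_fixtures(name: str):
    """Load a packaged fixture.

    * ``"table1"`` -- DataFrame of the 64 published NP-vesicle interaction
      energies and vesicle-membrane barrier heights (kJ/mol), transcribed
      from the source table; ``size_rank`` orders same-coating series whose
      sizes the table omits.
    * ``"generic_cell"`` -- the generic cell-surface :class:`SurfaceChemistry`.
    * ``"water"`` -- the default :class:`MediumSpec` (water, 310 K).
    """
    if name == "table1":
        ref = resources.files("nanoexo.data") / "table1_interaction_energies.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    if name == "generic_cell":
        return GENERIC_CELL
    if name == "water":
        return MediumSpec()
    raise ValueError(f"unknown fixture {name!r}; expected table1, generic_cell or water")


def read_cell_config(path: str | Path) -> dict:
    """Read the YAML cell/medium/physics configuration.

    Returns a dict with keys ``cell`` (SurfaceChemistry), ``medium``
    (MediumSpec), ``params`` (XdlvoParameters) and ``vesicle_rule``
    (VesicleRule); every field falls back to the packaged defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cell_raw = raw.get("cell", {})
    cell = SurfaceChemistry(
        name=cell_raw.get("name", "cell"),
        gamma_lw=float(cell_raw.get("gamma_lw", GENERIC_CELL.gamma_lw)),
        gamma_plus=float(cell_raw.get("gamma_plus", GENERIC_CELL.gamma_plus)),
        gamma_minus=float(cell_raw.get("gamma_minus", GENERIC_CELL.gamma_minus)),
        psi0=float(cell_raw.get("psi0_mv", GENERIC_CELL.psi0)),
    )
    med_raw = raw.get("medium", {})
    water = SurfaceChemistry(
        name="water",
        gamma_lw=float(med_raw.get("gamma_lw", WATER.gamma_lw)),
        gamma_plus=float(med_raw.get("gamma_plus", WATER.gamma_plus)),
        gamma_minus=float(med_raw.get("gamma_minus", WATER.gamma_minus)),
    )
    medium = MediumSpec(
        chemistry=water,
        relative_permittivity=float(med_raw.get("relative_permittivity", 74.0)),
        debye_length=float(med_raw.get("debye_length_nm", 0.78)),
        temperature=float(med_raw.get("temperature_k", 310.0)),
    )
    phys = raw.get("physics", {})
    params = XdlvoParameters(
        d0=float(phys.get("d0_nm", 0.157)),
        lambda_ab=float(phys.get("lambda_ab_nm", 0.6)),
        d_max=float(phys.get("d_max_nm", 20.0)),
        n_grid=int(phys.get("n_grid", 2000)),
    )
    vesicle_rule = VesicleRule(
        membrane_offset=float(raw.get("vesicle", {}).get("membrane_offset_nm", 0.0))
    )
    return {"cell": cell, "medium": medium, "params": params, "vesicle_rule": vesicle_rule}


def read_time_series(path: str | Path) -> pd.DataFrame:
    """Read an exocytosis time-series CSV.

    Columns: np_id, cell_line, time_h, amount_norm; one row per observation.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("np_id", "cell_line", "time_h", "amount_norm") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {', '.join(missing)}")
    return df


def save_models(models: Iterable[CellLineModel], path: str | Path) -> None:
    """Persist fitted cell-line models as a JSON store."""
    payload = {m.cell_line: dataclasses.asdict(m) for m in models}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_models(path: str | Path) -> dict[str, CellLineModel]:
    payload = json.loads(Path(path).read_text())
    return {name: CellLineModel(**fields) for name, fields in payload.items()}
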