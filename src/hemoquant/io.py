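"""File formats, run configuration, and batch quantification tables.

All tabular formats are comma-separated, dot-decimal, UTF-8 CSV with a
mandatory header; lines starting with ``#`` are provenance comments (config
hash and registry version) and are skipped on read.  The plate format has
``wavelength_nm`` as the first column and one column per sample id.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import calibration, quantify
from .calibration import REGISTRY_VERSION, QuantResult
from .pipeline import (
    GRADE_BOUNDS_UM,
    ICTERUS_PROMINENCE_AU,
    LIPEMIA_THRESHOLD_AU,
    PlasmaReport,
)
from .spectra import (
    DEFAULT_NOISE_SIGMA,
    DEFAULT_PATHLENGTH,
    DILUTION_GRID,
    PATHLENGTH_100UL,
    PATHLENGTH_200UL,
    AssayReadoutSet,
    MeasuredSpectrum,
    PanelSample,
    PyridineChannels,
)

__all__ = [
    "RunConfig",
    "read_plate_csv",
    "write_plate_csv",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_ground_truth_csv",
    "write_readouts_csv",
    "read_readouts_csv",
    "write_panel",
    "quantify_table",
    "write_report",
]

log = logging.getLogger("hemoquant")


# --------------------------------------------------------------------------- #
# run configuration
# --------------------------------------------------------------------------- #


@dataclass
class RunConfig:
    """Serializable pipeline configuration; all randomness flows from ``seed``."""

    seed: int = 0
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    pathlength_200ul_cm: float = PATHLENGTH_200UL
    pathlength_100ul_cm: float = PATHLENGTH_100UL
    dilution_grid: tuple[int, ...] = DILUTION_GRID
    linearity_tolerance_pct: float = 15.0
    lipemia_threshold_au: float = LIPEMIA_THRESHOLD_AU
    icterus_prominence_au: float = ICTERUS_PROMINENCE_AU
    grade_bounds_um: tuple[float, float] = GRADE_BOUNDS_UM
    eq1_parse: str = "printed"

    def __post_init__(self) -> None:
        for name in ("noise_sigma", "linearity_tolerance_pct",
                     "lipemia_threshold_au", "icterus_prominence_au"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eq1_parse not in quantify.EQ1_PARSES:
            raise ValueError(f"unknown eq1_parse {self.eq1_parse!r}")
        self.dilution_grid = tuple(int(d) for d in self.dilution_grid)
        self.grade_bounds_um = tuple(float(b) for b in self.grade_bounds_um)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dilution_grid"] = list(self.dilution_grid)
        d["grade_bounds_um"] = list(self.grade_bounds_um)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _provenance_header(config: Optional[RunConfig]) -> str:
    h = config.config_hash() if config is not None else "none"
    return f"# hemoquant registry_version={REGISTRY_VERSION} config_hash={h}\n"


# --------------------------------------------------------------------------- #
# plate and sheet formats
# --------------------------------------------------------------------------- #


def write_plate_csv(path, spectra: Mapping[str, MeasuredSpectrum],
                    config: Optional[RunConfig] = None) -> None:
    """Plate CSV: first column ``wavelength_nm``, one column per sample id."""
    if not spectra:
        raise ValueError("no spectra to write")
    ids = list(spectra)
    lam = spectra[ids[0]].wavelengths
    for sid in ids:
        if not np.array_equal(spectra[sid].wavelengths, lam):
            raise ValueError("all spectra must share one wavelength grid")
    table = pd.DataFrame({"wavelength_nm": lam})
    for sid in ids:
        table[sid] = spectra[sid].absorbance
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        table.to_csv(fh, index=False)


def read_plate_csv(path, sample_sheet: Optional[pd.DataFrame] = None) -> dict[str, MeasuredSpectrum]:
    """Read a plate CSV into one spectrum per sample column.

    Wavelengths must be strictly increasing and the body numeric.  When a
    sample sheet is given, its per-sample dilution factor and pathlength are
    attached; unknown sample ids in the sheet raise ``ValueError``.
    """
    table = pd.read_csv(path, comment="#")
    if table.columns[0] != "wavelength_nm":
        raise ValueError("first plate column must be wavelength_nm")
    try:
        values = table.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric plate body: {exc}") from exc
    lam = values["wavelength_nm"].to_numpy()
    if not np.all(np.diff(lam) > 0):
        raise ValueError("wavelengths must be strictly increasing")

    meta: dict[str, tuple[int, float]] = {}
    if sample_sheet is not None:
        sheet_ids = set(sample_sheet["sample_id"].astype(str))
        plate_ids = set(map(str, table.columns[1:]))
        unknown = sheet_ids - plate_ids
        if unknown:
            raise ValueError(f"sample sheet ids not on the plate: {sorted(unknown)}")
        for _, row in sample_sheet.iterrows():
            meta[str(row["sample_id"])] = (
                int(row.get("dilution_factor", 1)),
                float(row.get("pathlength_cm", DEFAULT_PATHLENGTH)),
            )

    spectra = {}
    for sid in map(str, table.columns[1:]):
        df, L = meta.get(sid, (1, DEFAULT_PATHLENGTH))
        spectra[sid] = MeasuredSpectrum(
            wavelengths=lam, absorbance=values[sid].to_numpy(),
            pathlength=L, dilution_factor=df,
        )
    return spectra


def write_sample_sheet(path, panel: Sequence[PanelSample],
                       config: Optional[RunConfig] = None) -> None:
    table = pd.DataFrame({
        "sample_id": [s.sample_id for s in panel],
        "dilution_factor": [s.spectrum.dilution_factor for s in panel],
        "pathlength_cm": [s.spectrum.pathlength for s in panel],
        "state": [s.state for s in panel],
        "seed": [s.spectrum.seed for s in panel],
    })
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        table.to_csv(fh, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ground_truth_csv(path, panel: Sequence[PanelSample],
                           config: Optional[RunConfig] = None) -> None:
    table = pd.DataFrame({
        "sample_id": [s.sample_id for s in panel],
        "state": [s.state for s in panel],
        "c_labile_heme_uM": [s.composition.c_labile_heme for s in panel],
        "c_hb_uM": [s.composition.c_hb for s in panel],
        "c_bilirubin_uM": [s.composition.c_bilirubin for s in panel],
        "turbidity_index": [s.composition.turbidity_index for s in panel],
    })
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        table.to_csv(fh, index=False)


_READOUT_COLUMNS = [
    "hak_A400", "harboe_A380", "harboe_A415", "harboe_A450",
    "pyridine_A556_red", "pyridine_A556_ox", "pyridine_A540_red",
    "pyridine_A557_red", "sls_A395", "sls_A413", "apohrp_nM",
    "direct_A380", "direct_A405",
]


def _readouts_to_row(r: AssayReadoutSet) -> list[float]:
    return [
        r.hak_A400, *r.harboe_triplet, *r.pyridine, *r.sls,
        r.apohrp_apparent_heme, *r.direct,
    ]


def _row_to_readouts(row: pd.Series) -> AssayReadoutSet:
    return AssayReadoutSet(
        hak_A400=float(row["hak_A400"]),
        harboe_triplet=(float(row["harboe_A380"]), float(row["harboe_A415"]),
                        float(row["harboe_A450"])),
        pyridine=PyridineChannels(
            float(row["pyridine_A556_red"]), float(row["pyridine_A556_ox"]),
            float(row["pyridine_A540_red"]), float(row["pyridine_A557_red"])),
        sls=(float(row["sls_A395"]), float(row["sls_A413"])),
        apohrp_apparent_heme=float(row["apohrp_nM"]),
        direct=(float(row["direct_A380"]), float(row["direct_A405"])),
    )


def write_readouts_csv(path, panel: Sequence[PanelSample],
                       config: Optional[RunConfig] = None) -> None:
    table = pd.DataFrame(
        [_readouts_to_row(s.readouts) for s in panel], columns=_READOUT_COLUMNS)
    table.insert(0, "sample_id", [s.sample_id for s in panel])
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        table.to_csv(fh, index=False)


def read_readouts_csv(path) -> dict[str, AssayReadoutSet]:
    table = pd.read_csv(path, comment="#")
    missing = set(_READOUT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"readout CSV missing columns: {sorted(missing)}")
    return {str(row["sample_id"]): _row_to_readouts(row)
            for _, row in table.iterrows()}


def write_panel(outdir, panel: Sequence[PanelSample],
                config: Optional[RunConfig] = None) -> dict[str, Path]:
    """Write a simulated panel as plate/sheet/truth/readout CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plate": outdir / "plate.csv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "readouts": outdir / "readouts.csv",
    }
    write_plate_csv(paths["plate"], {s.sample_id: s.spectrum for s in panel}, config)
    write_sample_sheet(paths["sample_sheet"], panel, config)
    write_ground_truth_csv(paths["ground_truth"], panel, config)
    write_readouts_csv(paths["readouts"], panel, config)
    log.info("panel of %d samples written to %s", len(panel), outdir)
    return paths


# --------------------------------------------------------------------------- #
# batch quantification
# --------------------------------------------------------------------------- #


def _quant_to_record(sid: str, res: QuantResult) -> dict:
    return {
        "sample_id": sid, "method": res.method, "analyte": res.analyte,
        "concentration": res.concentration, "assay_value": res.assay_value,
        "dilution_factor": res.dilution_factor,
        "flags": ";".join(sorted(res.flags)),
    }


def quantify_table(readouts: pd.DataFrame) -> pd.DataFrame:
    """Batch quantification of a long-format readout table.

    Expected columns: ``sample_id, method, channel, signal, dilution_factor``.
    Single-signal methods: ``direct_heme``, ``direct_hb``, ``heme_assay_kit``,
    ``apohrp_tmb``, ``apohrp_od``.  The ``harboe`` method takes three rows per
    sample with channels ``A380``, ``A415``, ``A450``.
    """
    needed = {"sample_id", "method", "channel", "signal", "dilution_factor"}
    missing = needed - set(readouts.columns)
    if missing:
        raise ValueError(f"readout table missing columns: {sorted(missing)}")
    records = []
    for (sid, method), grp in readouts.groupby(["sample_id", "method"], sort=True):
        df = float(grp["dilution_factor"].iloc[0])
        if method == "harboe":
            sig = {str(c): float(s) for c, s in zip(grp["channel"], grp["signal"])}
            try:
                res = quantify.harboe_hb(sig["A380"], sig["A415"], sig["A450"], df)
            except KeyError as exc:
                raise ValueError(f"sample {sid}: harboe needs channels "
                                 f"A380/A415/A450, missing {exc}") from exc
        else:
            signal = float(grp["signal"].iloc[0])
            if method == "direct_heme":
                res = quantify.uvvis_direct("heme", signal, df)
            elif method == "direct_hb":
                res = quantify.uvvis_direct("hemoglobin", signal, df)
            elif method == "heme_assay_kit":
                res = quantify.heme_assay_kit_total(signal, df)
            elif method == "apohrp_tmb":
                res = quantify.apohrp_quantify(signal, "TMB")
            elif method == "apohrp_od":
                res = quantify.apohrp_quantify(signal, "o-dianisidine")
            else:
                raise ValueError(f"unsupported method {method!r}")
        records.append(_quant_to_record(str(sid), res))
    return pd.DataFrame.from_records(records)


def write_report(out_prefix, report: PlasmaReport,
                 config: Optional[RunConfig] = None) -> tuple[Path, Path]:
    """Write a plasma report as TSV plus a JSON sidecar with full flags."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")
    with open(tsv_path, "w") as fh:
        fh.write(_provenance_header(config))
        report.to_dataframe().to_csv(fh, sep="\t", index=False)
    payload = report.to_dict()
    payload["registry_version"] = REGISTRY_VERSION
    payload["config_hash"] = config.config_hash() if config else None
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return tsv_path, json_path
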