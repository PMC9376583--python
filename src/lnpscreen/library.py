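"""Combinatorial LNP library enumeration, DLS quality control, and pooling.

A four-component lipid nanoparticle is defined by its ionizable lipid,
cholesterol variant, PEG-lipid, helper lipid, and the molar ratio of the
four. The screened library is the full Cartesian product of the component
lists; each formulation is assigned a unique DNA barcode. Before pooling,
every formulation is gated on dynamic-light-scattering measurements
(hydrodynamic diameter strictly between 20 and 200 nm and a monodisperse
autocorrelation function); only passing particles enter the injected pool.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

RATIO_TOL = 1e-6

#: Default component lists for the piperazine-lipid (PPZ) screen: 8 ionizable
#: lipids x 2 cholesterol variants x 2 PEG-lipids x 1 helper x 4 molar ratios
#: = 128 formulations.
DEFAULT_LIPIDS = (
    "PPZ-A10", "PPZ-A11", "PPZ-A12", "PPZ-A18-2Z",
    "PPZ-B10", "PPZ-B11", "PPZ-B12", "PPZ-B18-2Z",
)
DEFAULT_CHOLESTEROLS = ("cholesterol", "20a-OH-cholesterol")
DEFAULT_PEGS = ("C14PEG2K", "C18PEG2K")
DEFAULT_HELPER = "DOPE"
#: Molar ratios as (ionizable, cholesterol, PEG, helper) percentages.
DEFAULT_RATIOS = (
    (30.0, 30.0, 1.0, 39.0),
    (35.0, 46.5, 2.5, 16.0),
    (45.0, 39.5, 2.5, 13.0),
    (50.0, 35.0, 2.5, 12.5),
)


def ratio_label(ratio: Sequence[float]) -> str:
    return ":".join(f"{x:g}" for x in ratio)


def _validate_ratio(ratio: Sequence[float]) -> tuple[float, ...]:
    ratio = tuple(float(x) for x in ratio)
    if len(ratio) != 4:
        raise ValueError(f"molar ratio must have 4 entries, got {ratio}")
    if any(x <= 0 for x in ratio):
        raise ValueError(f"molar ratio entries must be strictly positive: {ratio}")
    if abs(sum(ratio) - 100.0) > RATIO_TOL:
        raise ValueError(
            f"molar ratio {ratio_label(ratio)} sums to {sum(ratio):g}, expected 100"
        )
    return ratio


@dataclass(frozen=True)
class Formulation:
    """One LNP design plus its barcode assignment."""

    lnp_id: str
    ionizable_lipid: str
    cholesterol_variant: str
    peg_lipid: str
    helper_lipid: str
    molar_ratio: tuple[float, float, float, float]
    barcode_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "molar_ratio", _validate_ratio(self.molar_ratio))

    def component(self, axis: str) -> str:
        """Level of this formulation on a component axis."""
        if axis == "molar_ratio":
            return ratio_label(self.molar_ratio)
        if axis in ("ionizable_lipid", "cholesterol_variant", "peg_lipid",
                    "helper_lipid"):
            return getattr(self, axis)
        raise ValueError(f"unknown component axis: {axis!r}")


COMPONENT_AXES = ("ionizable_lipid", "cholesterol_variant", "peg_lipid", "molar_ratio")


def enumerate_formulations(
    lipids: Sequence[str] = DEFAULT_LIPIDS,
    cholesterols: Sequence[str] = DEFAULT_CHOLESTEROLS,
    pegs: Sequence[str] = DEFAULT_PEGS,
    helper: str = DEFAULT_HELPER,
    ratios: Sequence[Sequence[float]] = DEFAULT_RATIOS,
    barcode_ids: Sequence[str] | None = None,
) -> list[Formulation]:
    """Enumerate the full combinatorial library in deterministic order.

    Order is the nested product (lipid, cholesterol, PEG, ratio) with the
    ratio varying fastest; barcode ids are assigned in that order (generated
    ``BC..`` labels unless supplied).
    """
    for name, lst in (("lipids", lipids), ("cholesterols", cholesterols),
                      ("pegs", pegs), ("ratios", ratios)):
        if not lst:
            raise ValueError(f"component list {name!r} is empty")
    ratios = [_validate_ratio(r) for r in ratios]
    n = len(lipids) * len(cholesterols) * len(pegs) * len(ratios)
    if barcode_ids is None:
        width = max(2, len(str(n)))
        barcode_ids = [f"BC{i + 1:0{width}d}" for i in range(n)]
    if len(barcode_ids) < n:
        raise ValueError(f"need {n} barcode ids, got {len(barcode_ids)}")
    out = []
    width = max(3, len(str(n)))
    for i, (lip, chol, peg, ratio) in enumerate(
        itertools.product(lipids, cholesterols, pegs, ratios)
    ):
        out.append(
            Formulation(
                lnp_id=f"LNP{i + 1:0{width}d}",
                ionizable_lipid=lip,
                cholesterol_variant=chol,
                peg_lipid=peg,
                helper_lipid=helper,
                molar_ratio=ratio,
                barcode_id=barcode_ids[i],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCRecord:
    """Dynamic-light-scattering QC measurements for one formulation.

    ``monodisperse`` captures the instrument's stable-autocorrelation /
    single-inflection-point judgment. When only a polydispersity index is
    available, monodispersity is derived as ``pdi <= pdi_max`` at gating time.
    """

    lnp_id: str
    diameter_nm: float
    monodisperse: bool | None = None
    pdi: float | None = None

    def passes(self, d_min_nm: float = 20.0, d_max_nm: float = 200.0,
               pdi_max: float = 0.3) -> bool:
        """Strict-inequality diameter gate plus monodispersity."""
        if self.monodisperse is not None:
            mono = self.monodisperse
        elif self.pdi is not None:
            mono = self.pdi <= pdi_max
        else:
            raise ValueError(
                f"QC record for {self.lnp_id} has neither a monodispersity "
                "flag nor a PDI"
            )
        return (d_min_nm < self.diameter_nm < d_max_nm) and mono


def apply_qc(
    formulations: Sequence[Formulation],
    qc_table: Sequence[QCRecord],
    d_min_nm: float = 20.0,
    d_max_nm: float = 200.0,
    pdi_max: float = 0.3,
) -> tuple[list[Formulation], list[Formulation]]:
    """Partition formulations into (pass, fail) by the DLS gate.

    Every formulation must have exactly one QC record; missing or duplicate
    records raise with the offending lnp_ids listed.
    """
    by_id: dict[str, QCRecord] = {}
    dupes = []
    for rec in qc_table:
        if rec.lnp_id in by_id:
            dupes.append(rec.lnp_id)
        by_id[rec.lnp_id] = rec
    missing = [f.lnp_id for f in formulations if f.lnp_id not in by_id]
    if missing or dupes:
        raise ValueError(
            f"QC table mismatch — missing records: {missing}; duplicates: {dupes}"
        )
    passed, failed = [], []
    for f in formulations:
        rec = by_id[f.lnp_id]
        (passed if rec.passes(d_min_nm, d_max_nm, pdi_max) else failed).append(f)
    return passed, failed


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenPool:
    """The injected mixture: member LNPs plus one unencapsulated control.

    The naked control barcode is sequenced in the input and therefore takes a
    share of ``input_proportions``, but it is not an LNP and does not share
    the per-particle dose.
    """

    members: tuple[str, ...]                    # lnp_ids passing QC
    member_barcodes: tuple[str, ...]            # parallel barcode ids
    control_barcode_id: str
    input_proportions: Mapping[str, float]      # barcode_id -> fraction
    total_dose_mg_per_kg: float
    per_particle_dose_mg_per_kg: float = field(init=False)
    mrna_to_barcode_mass_ratio: float = 10.0

    def __post_init__(self) -> None:
        total = sum(self.input_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"input proportions sum to {total!r}, expected 1")
        expected_keys = set(self.member_barcodes) | {self.control_barcode_id}
        if set(self.input_proportions) != expected_keys:
            raise ValueError("input proportions must cover members + control exactly")
        object.__setattr__(
            self,
            "per_particle_dose_mg_per_kg",
            self.total_dose_mg_per_kg / len(self.members),
        )

    @property
    def barcode_ids(self) -> tuple[str, ...]:
        return self.member_barcodes + (self.control_barcode_id,)


def build_pool(
    pass_list: Sequence[Formulation],
    control_barcode_id: str,
    total_dose_mg_per_kg: float = 1.5,
    proportions: Mapping[str, float] | None = None,
    mrna_to_barcode_mass_ratio: float = 10.0,
) -> ScreenPool:
    """Build the injected pool from the QC-passing formulations.

    With no explicit proportions, every barcode (members and the naked
    control) contributes equally: 1/(N+1) each. A 65-member pool at a total
    dose of 1.5 mg/kg gives 1.5/65 ≈ 0.023 mg nucleic acid per kg per
    particle.
    """
    if not pass_list:
        raise ValueError("cannot build a pool from an empty pass list")
    member_barcodes = tuple(f.barcode_id for f in pass_list)
    if control_barcode_id in member_barcodes:
        raise ValueError("control barcode collides with a member barcode")
    keys = list(member_barcodes) + [control_barcode_id]
    if proportions is None:
        proportions = {k: 1.0 / len(keys) for k in keys}
    else:
        missing = set(keys) - set(proportions)
        if missing:
            raise ValueError(f"proportions missing barcodes: {sorted(missing)}")
        total = sum(proportions[k] for k in keys)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total!r}, expected 1")
        proportions = {k: float(proportions[k]) for k in keys}
    return ScreenPool(
        members=tuple(f.lnp_id for f in pass_list),
        member_barcodes=member_barcodes,
        control_barcode_id=control_barcode_id,
        input_proportions=proportions,
        total_dose_mg_per_kg=float(total_dose_mg_per_kg),
        mrna_to_barcode_mass_ratio=float(mrna_to_barcode_mass_ratio),
    )


# ---------------------------------------------------------------------------
# Table I/O (round-trips byte-identically)
# ---------------------------------------------------------------------------


def formulations_to_frame(formulations: Sequence[Formulation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnp_id": [f.lnp_id for f in formulations],
            "ionizable_lipid": [f.ionizable_lipid for f in formulations],
            "cholesterol_variant": [f.cholesterol_variant for f in formulations],
            "peg_lipid": [f.peg_lipid for f in formulations],
            "helper_lipid": [f.helper_lipid for f in formulations],
            "molar_ratio": [ratio_label(f.molar_ratio) for f in formulations],
            "barcode_id": [f.barcode_id for f in formulations],
        }
    )


def formulations_from_frame(df: pd.DataFrame) -> list[Formulation]:
    return [
        Formulation(
            lnp_id=row.lnp_id,
            ionizable_lipid=row.ionizable_lipid,
            cholesterol_variant=row.cholesterol_variant,
            peg_lipid=row.peg_lipid,
            helper_lipid=row.helper_lipid,
            molar_ratio=tuple(float(x) for x in row.molar_ratio.split(":")),
            barcode_id=row.barcode_id,
        )
        for row in df.itertuples()
    ]


def write_formulations(formulations: Sequence[Formulation], path: str | Path) -> None:
    formulations_to_frame(formulations).to_csv(path, sep="\t", index=False)


def read_formulations(path: str | Path) -> list[Formulation]:
    return formulations_from_frame(pd.read_csv(path, sep="\t", comment="#"))


def qc_to_frame(records: Sequence[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnp_id": [r.lnp_id for r in records],
            "diameter_nm": [r.diameter_nm for r in records],
            "monodisperse": [r.monodisperse for r in records],
            "pdi": [r.pdi for r in records],
        }
    )


def qc_from_frame(df: pd.DataFrame) -> list[QCRecord]:
    out = []
    for row in df.itertuples():
        mono = row.monodisperse
        if pd.isna(mono):
            mono = None
        elif isinstance(mono, str):
            mono = mono.strip().lower() in ("true", "1", "yes")
        else:
            mono = bool(mono)
        pdi = None if pd.isna(row.pdi) else float(row.pdi)
        out.append(
            QCRecord(
                lnp_id=row.lnp_id,
                diameter_nm=float(row.diameter_nm),
                monodisperse=mono,
                pdi=pdi,
            )
        )
    return out


def write_qc(records: Sequence[QCRecord], path: str | Path) -> None:
    qc_to_frame(records).to_csv(path, sep="\t", index=False)


def read_qc(path: str | Path) -> list[QCRecord]:
    return qc_from_frame(
        pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    )


def pool_to_frame(pool: ScreenPool) -> pd.DataFrame:
    rows = []
    lnp_by_barcode = dict(zip(pool.member_barcodes, pool.members))
    for bid in pool.barcode_ids:
        rows.append(
            {
                "barcode_id": bid,
                "lnp_id": lnp_by_barcode.get(bid, "control"),
                "input_proportion": pool.input_proportions[bid],
                "is_control": bid == pool.control_barcode_id,
            }
        )
    return pd.DataFrame(rows)


def write_pool(pool: ScreenPool, path: str | Path) -> None:
    df = pool_to_frame(pool)
    df.attrs["total_dose_mg_per_kg"] = pool.total_dose_mg_per_kg
    with open(path, "w") as fh:
        fh.write(f"# total_dose_mg_per_kg={pool.total_dose_mg_per_kg}\n")
        fh.write(
            f"# mrna_to_barcode_mass_ratio={pool.mrna_to_barcode_mass_ratio}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_pool(path: str | Path) -> ScreenPool:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            try:
                meta[key.strip()] = float(value)
            except ValueError:
                pass
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    control = df.loc[df.is_control, "barcode_id"].iloc[0]
    members_df = df.loc[~df.is_control]
    return ScreenPool(
        members=tuple(members_df.lnp_id),
        member_barcodes=tuple(members_df.barcode_id),
        control_barcode_id=control,
        input_proportions=dict(zip(df.barcode_id, df.input_proportion)),
        total_dose_mg_per_kg=meta.get("total_dose_mg_per_kg", 1.5),
        mrna_to_barcode_mass_ratio=meta.get("mrna_to_barcode_mass_ratio", 10.0),
    )
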