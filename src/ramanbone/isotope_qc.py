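"""Wet-chemistry formulas and protein-survival QC flags.

Atomic C:N = (%C/%N) x 1.1666, with values inside 2.9-3.6 indicative of
preserved bone protein; collagen yields below ~1-2 % w/w are suspect for
stable-isotope work; samples delivering 7 ug nitrogen or less to the mass
spectrometer are insufficient for a nitrogen determination.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "IsotopeResult",
    "QCFlags",
    "CN_MASS_FACTOR",
    "CN_RANGE",
    "COLLAGEN_FLOOR_PCT",
    "NITROGEN_FLOOR_UG",
    "atomic_cn",
    "delta_ratio",
    "qc_flags",
]

#: Mass-to-atomic conversion for the C:N ratio (ratio of N to C molar mass).
CN_MASS_FACTOR = 1.1666

#: Atomic C:N interval consistent with preserved bone protein (inclusive).
CN_RANGE = (2.9, 3.6)

#: Collagen yields below this % w/w are suspect.  The operational screening
#: narrative uses > 1 %; the cautious upper end of the conventional 1-2 %
#: band can be passed explicitly.
COLLAGEN_FLOOR_PCT = 1.0

#: Nitrogen delivered to the spectrometer at or below this (ug) is
#: insufficient for a nitrogen isotope determination.
NITROGEN_FLOOR_UG = 7.0


@dataclass(frozen=True)
class IsotopeResult:
    """One wet-chemistry record.

    ``pct_collagen`` is the gelatin yield relative to the undemineralised
    starting bone weight; delta values are per mil vs V-PDB (carbon) and
    AIR (nitrogen).
    """

    sample_id: str
    pct_n: float
    pct_c: float
    cn_atomic: float | None = None
    pct_collagen: float | None = None
    d13c: float | None = None
    d15n: float | None = None
    nitrogen_mass_ug: float | None = None

    def __post_init__(self) -> None:
        for name in ("pct_n", "pct_c", "pct_collagen"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class QCFlags:
    cn_out_of_range: bool
    collagen_suspect: bool
    nitrogen_insufficient: bool


def atomic_cn(pct_c: float, pct_n: float) -> float:
    """Atomic C:N ratio from weight percents: (%C / %N) x 1.1666.

    Undefined at %N = 0 (the partial-table case where no nitrogen
    determination exists).
    """
    if pct_n <= 0:
        raise ValueError("atomic C:N undefined for pct_n <= 0")
    return (pct_c / pct_n) * CN_MASS_FACTOR


def delta_ratio(r_sample: float, r_standard: float) -> float:
    """Delta notation in per mil: (R_sample / R_standard - 1) x 1000.

    Expresses a sample's isotope abundance ratio relative to the
    international standard analysed alongside it (V-PDB for 13C/12C,
    AIR for 15N/14N).
    """
    if r_standard <= 0:
        raise ValueError("r_standard must be > 0")
    return (r_sample / r_standard - 1.0) * 1000.0


def qc_flags(
    result: IsotopeResult,
    cn_range: tuple[float, float] = CN_RANGE,
    collagen_floor: float = COLLAGEN_FLOOR_PCT,
    nitrogen_floor: float = NITROGEN_FLOOR_UG,
) -> QCFlags:
    """Protein-survival QC flags for one record.

    ``cn_out_of_range``: atomic C:N outside the (inclusive) preserved-protein
    interval, computed from %C/%N when not stored on the record.
    ``collagen_suspect``: yield below ``collagen_floor`` % w/w.
    ``nitrogen_insufficient``: nitrogen mass at or below ``nitrogen_floor``
    ug, when known.
    """
    cn = result.cn_atomic
    if cn is None and result.pct_n > 0:
        cn = atomic_cn(result.pct_c, result.pct_n)
    cn_bad = cn is None or not (cn_range[0] <= cn <= cn_range[1])
    collagen_bad = (
        result.pct_collagen is not None and result.pct_collagen < collagen_floor
    )
    nitrogen_bad = (
        result.nitrogen_mass_ug is not None
        and result.nitrogen_mass_ug <= nitrogen_floor
    )
    return QCFlags(
        cn_out_of_range=bool(cn_bad),
        collagen_suspect=bool(collagen_bad),
        nitrogen_insufficient=bool(nitrogen_bad),
    )
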