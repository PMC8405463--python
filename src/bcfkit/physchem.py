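"""pH-dependent speciation and hydrophobicity of ionizable bases.

SSRIs and their N-desmethyl metabolites are monoprotic amine bases.  At a
given pH only the neutral (unionized) fraction partitions into octanol-like
phases, so the effective hydrophobicity is the distribution coefficient

    log D = log Kow + log10( 1 / (1 + 10**(pKa - pH)) )

(Henderson-Hasselbalch, base form).  This module provides that speciation
arithmetic, a compound-properties container, the regulatory bioaccumulation
classification (BCF > 2000 -> "bioaccumulative"), and a reader for delimited
compound tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, LinkageError

__all__ = [
    "CompoundProperties",
    "neutral_fraction",
    "log_d",
    "classify_reach",
    "load_compounds",
    "ssri_panel",
    "DEFAULT_PH",
    "REACH_BCF_THRESHOLD",
]

#: Experimental pH of the exposure medium (7.8 +/- 0.2 in the assay design).
DEFAULT_PH = 7.8

#: Regulatory threshold: a substance with BCF strictly above this value
#: (L/kg) is classed as bioaccumulative.
REACH_BCF_THRESHOLD = 2000.0


@dataclass(frozen=True)
class CompoundProperties:
    """Identity and physico-chemical constants of one analyte.

    Parameters
    ----------
    name : str
        Analyte identifier (e.g. ``"fluoxetine"``).
    pka : float
        Acid dissociation constant of the conjugate acid (monoprotic base),
        dimensionless, must lie in (0, 14).
    log_kow : float
        log10 octanol-water partition coefficient of the neutral species.
    role : {"parent", "metabolite"}
    parent : str, optional
        For a metabolite, the identifier of its parent compound.
    lc50 : float, optional
        Median lethal concentration in ug/L; used to derive nominal
        exposure levels.
    """

    name: str
    pka: float
    log_kow: float
    role: str = "parent"
    parent: str | None = None
    lc50: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("compound name must be non-empty")
        if not (math.isfinite(self.pka) and 0.0 < self.pka < 14.0):
            raise InvalidInputError(
                f"{self.name}: pKa must be finite and in (0, 14), got {self.pka}"
            )
        if not math.isfinite(self.log_kow):
            raise InvalidInputError(f"{self.name}: log Kow must be finite")
        if self.role not in ("parent", "metabolite"):
            raise InvalidInputError(
                f"{self.name}: role must be 'parent' or 'metabolite', got {self.role!r}"
            )
        if self.role == "metabolite" and not self.parent:
            raise LinkageError(f"metabolite {self.name} must link to exactly one parent")
        if self.role == "parent" and self.parent:
            raise LinkageError(f"parent compound {self.name} must not carry a parent link")
        if self.lc50 is not None and not (math.isfinite(self.lc50) and self.lc50 > 0):
            raise InvalidInputError(f"{self.name}: LC50 must be positive when present")

    def log_d(self, ph: float = DEFAULT_PH) -> float:
        """Distribution coefficient of this compound at the given pH."""
        return log_d(self.log_kow, self.pka, ph)


def _check_finite(**kwargs: float) -> None:
    for key, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"{key} must be finite, got {value!r}")


def neutral_fraction(pka, ph):
    """Fraction of a monoprotic base present in the neutral form at ``ph``.

    Henderson-Hasselbalch for bases: ``1 / (1 + 10**(pka - ph))``.  Strictly
    increasing in pH and decreasing in pKa; returns a value in (0, 1).

    Parameters
    ----------
    pka, ph : float or array-like
        Dissociation constant and medium pH; must be finite.
    """
    _check_finite(pka=pka, ph=ph)
    pka = np.asarray(pka, dtype=float)
    ph = np.asarray(ph, dtype=float)
    frac = 1.0 / (1.0 + np.power(10.0, pka - ph))
    if frac.ndim == 0:
        return float(frac)
    return frac


def log_d(log_kow, pka, ph=DEFAULT_PH):
    """pH-dependent log distribution coefficient of a monoprotic base.

    ``log D = log Kow + log10(neutral_fraction(pka, ph))``; always at most
    ``log Kow`` because the ionized form is assumed not to partition.
    """
    _check_finite(log_kow=log_kow, pka=pka, ph=ph)
    log_kow = np.asarray(log_kow, dtype=float)
    out = log_kow + np.log10(neutral_fraction(pka, ph))
    if out.ndim == 0:
        return float(out)
    return out


def classify_reach(bcf: float) -> str:
    """Regulatory bioaccumulation category for a bioconcentration factor.

    Returns ``"bioaccumulative"`` iff ``bcf`` is strictly above 2000 L/kg,
    else ``"not_bioaccumulative"``.  The boundary value 2000 itself is not
    bioaccumulative.
    """
    _check_finite(bcf=bcf)
    if bcf < 0:
        raise InvalidInputError(f"BCF must be non-negative, got {bcf}")
    return "bioaccumulative" if bcf > REACH_BCF_THRESHOLD else "not_bioaccumulative"


# Physico-chemical constants of the four SSRIs and their three N-desmethyl
# metabolites (pKa from SciFinder, log Kow from EPI Suite / ChemAxon).
_SSRI_PANEL = (
    CompoundProperties("fluoxetine", pka=10.10, log_kow=4.65),
    CompoundProperties("norfluoxetine", pka=9.05, log_kow=2.05,
                       role="metabolite", parent="fluoxetine"),
    CompoundProperties("sertraline", pka=9.48, log_kow=5.29),
    CompoundProperties("norsertraline", pka=9.05, log_kow=4.72,
                       role="metabolite", parent="sertraline"),
    CompoundProperties("citalopram", pka=9.50, log_kow=3.74),
    CompoundProperties("desmethylcitalopram", pka=10.54, log_kow=3.38,
                       role="metabolite", parent="citalopram"),
    CompoundProperties("paroxetine", pka=9.90, log_kow=3.95),
)


def ssri_panel() -> dict[str, CompoundProperties]:
    """Built-in compound table for the SSRI study panel (7 analytes)."""
    return {c.name: c for c in _SSRI_PANEL}


def load_compounds(path: str | Path, sep: str | None = None) -> dict[str, CompoundProperties]:
    """Read a delimited compound-properties table.

    Expected columns: ``name, role, parent, pka, log_kow, lc50`` (``parent``
    and ``lc50`` may be empty).  Delimiter is sniffed unless ``sep`` is given.
    Metabolite parent links are validated against the table.
    """
    df = pd.read_csv(path, sep=sep, engine="python", skipinitialspace=True)
    required = {"name", "pka", "log_kow"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    compounds: dict[str, CompoundProperties] = {}
    for _, row in df.iterrows():
        parent = row.get("parent")
        if parent is not None and (pd.isna(parent) or parent == ""):
            parent = None
        lc50 = row.get("lc50")
        if lc50 is not None and pd.isna(lc50):
            lc50 = None
        comp = CompoundProperties(
            name=str(row["name"]),
            pka=float(row["pka"]),
            log_kow=float(row["log_kow"]),
            role=str(row.get("role", "parent") or "parent"),
            parent=None if parent is None else str(parent),
            lc50=None if lc50 is None else float(lc50),
        )
        compounds[comp.name] = comp
    for comp in compounds.values():
        if comp.parent is not None and comp.parent not in compounds:
            raise LinkageError(
                f"metabolite {comp.name} links to unknown parent {comp.parent!r}"
            )
    return compounds
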