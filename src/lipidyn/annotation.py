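"""Lipid species name parsing and physicochemical annotation.

Targeted plasma lipidomics platforms report species by subclass and fatty-acyl
composition, e.g. ``LPC(16:0)``, ``PE(P-18:0/22:6)`` or — for triacylglycerols,
where one fatty acid is resolved within each transition — ``TAG52:2-FA18:1``.
This module parses those names into structured identities and derives the
annotation catalog (saturation, omega class, chain parity, constituent fatty
acids, detailed subclass incl. small/large TAG) that the enrichment layer
consumes.

Omega classification cannot be inferred from a ``carbons:double_bonds`` pair
alone (it depends on double-bond position), so it is driven by a fixed lookup
table shipped with the package; fatty acids absent from the table are labelled
``unknown`` rather than guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FattyAcyl",
    "LipidSpecies",
    "LipidAnnotation",
    "LipidParseError",
    "parse_lipid_name",
    "classify_tag_size",
    "aggregate_tag_species",
    "annotate",
    "load_omega_lookup",
    "build_annotation_catalog",
    "SINGLE_ACYL_CLASSES",
    "DUAL_ACYL_CLASSES",
    "EXCLUDED_CLASSES",
    "ANALYSIS_CLASSES",
]

#: Subclasses carrying exactly one fatty acyl.
SINGLE_ACYL_CLASSES = frozenset(
    {"FFA", "CE", "LPC", "LPE", "SM", "CER", "DCER", "HCER", "LCER",
     "LPA", "LPG", "LPS", "LPI"}
)
#: Glycerophospholipid / diacyl subclasses carrying two fatty acyls.
DUAL_ACYL_CLASSES = frozenset({"PC", "PE", "PI", "DAG", "PA", "PG", "PS"})
#: Classes parsed but excluded from downstream analysis (poor DMS separation
#: or excessive missingness on this platform).
EXCLUDED_CLASSES = frozenset({"PA", "LPA", "PG", "LPG", "PS", "LPS"})
#: The 16 subclasses retained for analysis.
ANALYSIS_CLASSES = frozenset(
    {"FFA", "TAG", "DAG", "CE", "PC", "LPC", "PE", "PE-O", "PE-P", "LPE",
     "SM", "PI", "CER", "DCER", "HCER", "LCER"}
)

_ALL_CLASSES = SINGLE_ACYL_CLASSES | DUAL_ACYL_CLASSES | {"PE-O", "PE-P", "TAG"}


class LipidParseError(ValueError):
    """Raised when a lipid name does not match any accepted dialect."""


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl chain: carbon count and number of C=C double bonds."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"acyl carbons must be >= 1, got {self.carbons}")
        if not 0 <= self.double_bonds < self.carbons:
            raise ValueError(
                f"double bonds must satisfy 0 <= d < carbons, got "
                f"{self.double_bonds}:{self.carbons}"
            )

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @property
    def saturation(self) -> str:
        """SFA (0 double bonds), MUFA (1) or PUFA (>=2)."""
        if self.double_bonds == 0:
            return "SFA"
        if self.double_bonds == 1:
            return "MUFA"
        return "PUFA"

    @property
    def parity(self) -> str:
        return "odd-chain" if self.carbons % 2 else "even-chain"


@dataclass(frozen=True)
class LipidSpecies:
    """Structured identity of one lipid species.

    ``acyls`` holds the constituent fatty acyls for all classes except TAG,
    where only the total composition plus one named FA is resolved by the
    scheduled transition; there ``acyls`` is empty, ``total`` holds the summed
    (carbons, double_bonds) and ``named_fa`` the resolved FA.
    """

    name: str
    subclass: str
    acyls: tuple[FattyAcyl, ...] = ()
    named_fa: FattyAcyl | None = None
    total: tuple[int, int] | None = None
    ether_linkage: str = "none"  # none | alkyl | alkenyl

    def __post_init__(self) -> None:
        if self.ether_linkage != "none" and self.subclass not in ("PE-O", "PE-P"):
            raise ValueError("ether linkage only valid for PE-O/PE-P")
        if self.subclass == "TAG":
            if self.named_fa is None or self.total is None:
                raise ValueError("TAG species need total composition and named FA")
        elif self.subclass in SINGLE_ACYL_CLASSES and len(self.acyls) != 1:
            raise ValueError(f"{self.subclass} carries exactly one acyl")

    @property
    def total_carbons(self) -> int:
        if self.total is not None:
            return self.total[0]
        return sum(a.carbons for a in self.acyls)

    @property
    def total_double_bonds(self) -> int:
        if self.total is not None:
            return self.total[1]
        return sum(a.double_bonds for a in self.acyls)

    @property
    def has_identical_fas(self) -> bool:
        """True for complex lipids whose two acyls are the same FA.

        Fragment-ion signal from such species is doubled, which the
        quantification layer corrects for.
        """
        return len(self.acyls) == 2 and self.acyls[0] == self.acyls[1]

    def canonical_name(self) -> str:
        if self.subclass == "TAG":
            t = self.total
            return f"TAG{t[0]}:{t[1]}-FA{self.named_fa}"
        if self.subclass == "PE-O":
            return f"PE(O-{self.acyls[0]}/{self.acyls[1]})"
        if self.subclass == "PE-P":
            return f"PE(P-{self.acyls[0]}/{self.acyls[1]})"
        inner = "/".join(str(a) for a in self.acyls)
        return f"{self.subclass}({inner})"


@dataclass(frozen=True)
class LipidAnnotation:
    """Physicochemical annotation of one species, one flag set per family."""

    species: str
    subclass: str
    total_carbons: int
    total_double_bonds: int
    tag_size: str  # small | large | not-applicable
    saturation_set: frozenset[str]
    omega_set: frozenset[str]
    parity_set: frozenset[str]
    fa_set: frozenset[FattyAcyl]
    subclass_detailed: str


_CD = r"(\d+):(\d+)"
_RE_TAG = re.compile(rf"^TAG{_CD}-FA{_CD}$")
_RE_ETHER = re.compile(rf"^PE\(([OP])-{_CD}/{_CD}\)$")
_RE_DUAL = re.compile(rf"^([A-Za-z]+)\({_CD}/{_CD}\)$")
_RE_SINGLE = re.compile(rf"^([A-Za-z]+)\({_CD}\)$")


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a lipid name in any accepted dialect into a :class:`LipidSpecies`.

    Accepted dialects: ``CLASS(c:d)``, ``CLASS(c:d/c:d)``, ``PE(O-c:d/c:d)``,
    ``PE(P-c:d/c:d)`` and ``TAGt:d-FAc:d``.  ``FA(c:d)`` is accepted as an
    alias for free fatty acids and canonicalized to ``FFA(c:d)``.

    Raises
    ------
    LipidParseError
        If the name matches no dialect or uses an unknown class prefix.
    """
    name = name.strip()
    m = _RE_TAG.match(name)
    if m:
        t_c, t_d, f_c, f_d = map(int, m.groups())
        named = FattyAcyl(f_c, f_d)
        if named.carbons > t_c:
            raise LipidParseError(f"named FA exceeds TAG total in {name!r}")
        return LipidSpecies(name=f"TAG{t_c}:{t_d}-FA{named}", subclass="TAG",
                            named_fa=named, total=(t_c, t_d))
    m = _RE_ETHER.match(name)
    if m:
        kind, c1, d1, c2, d2 = m.groups()
        sub = "PE-O" if kind == "O" else "PE-P"
        linkage = "alkyl" if kind == "O" else "alkenyl"
        acyls = (FattyAcyl(int(c1), int(d1)), FattyAcyl(int(c2), int(d2)))
        return LipidSpecies(name=name, subclass=sub, acyls=acyls,
                            ether_linkage=linkage)
    m = _RE_DUAL.match(name)
    if m:
        cls, c1, d1, c2, d2 = m.groups()
        cls = cls.upper()
        if cls not in DUAL_ACYL_CLASSES:
            raise LipidParseError(f"unsupported two-acyl class {cls!r} in {name!r}")
        acyls = (FattyAcyl(int(c1), int(d1)), FattyAcyl(int(c2), int(d2)))
        return LipidSpecies(name=f"{cls}({acyls[0]}/{acyls[1]})",
                            subclass=cls, acyls=acyls)
    m = _RE_SINGLE.match(name)
    if m:
        cls, c, d = m.groups()
        cls = cls.upper()
        if cls == "FA":
            cls = "FFA"
        if cls not in SINGLE_ACYL_CLASSES:
            raise LipidParseError(f"unsupported single-acyl class {cls!r} in {name!r}")
        acyl = FattyAcyl(int(c), int(d))
        return LipidSpecies(name=f"{cls}({acyl})", subclass=cls, acyls=(acyl,))
    raise LipidParseError(f"unparseable lipid name {name!r}")


def classify_tag_size(total_carbons: int) -> str:
    """Small vs large TAG: <=48 summed acyl carbons is small, >=49 large."""
    if total_carbons < 1:
        raise ValueError("total carbons must be >= 1")
    return "small" if total_carbons <= 48 else "large"


def aggregate_tag_species(conc: pd.DataFrame) -> pd.DataFrame:
    """Aggregate FA-resolved TAG species to (total carbons, double bonds) groups.

    Concentrations must be untransformed; member species of a group are summed
    per sample, propagating NaN only when every member is missing.  Non-TAG
    columns pass through unchanged.  Column order: non-TAG columns first (input
    order), then TAG groups sorted by name.
    """
    tag_cols: dict[str, list[str]] = {}
    other_cols: list[str] = []
    for col in conc.columns:
        sp = parse_lipid_name(col)
        if sp.subclass == "TAG":
            key = f"TAG{sp.total[0]}:{sp.total[1]}"
            tag_cols.setdefault(key, []).append(col)
        else:
            other_cols.append(col)
    out = conc[other_cols].copy()
    for key in sorted(tag_cols):
        out[key] = conc[tag_cols[key]].sum(axis=1, min_count=1)
    return out


def load_omega_lookup(path=None) -> dict[FattyAcyl, str]:
    """Load the FA -> omega-class lookup from a two-column CSV (``fa,omega``).

    Defaults to the table shipped with the package.  FAs with ambiguous
    double-bond position (e.g. 18:3, 22:5) are deliberately absent from the
    shipped table and resolve to ``unknown``.
    """
    if path is None:
        ref = resources.files("lipidyn.data").joinpath("omega_lookup.csv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    lookup = {}
    for fa, omega in zip(table["fa"], table["omega"]):
        c, d = fa.split(":")
        lookup[FattyAcyl(int(c), int(d))] = omega
    return lookup


def _constituent_fas(species: LipidSpecies) -> tuple[FattyAcyl, ...]:
    if species.subclass == "TAG":
        return (species.named_fa,)
    return species.acyls


def annotate(
    species: LipidSpecies,
    omega_lookup: Mapping[FattyAcyl, str] | None = None,
) -> LipidAnnotation:
    """Derive the full physicochemical annotation for one parsed species."""
    if omega_lookup is None:
        omega_lookup = load_omega_lookup()
    fas = _constituent_fas(species)
    saturation = frozenset(fa.saturation for fa in fas)
    parity = frozenset(fa.parity for fa in fas)
    omega = frozenset(omega_lookup.get(fa, "unknown") for fa in fas)
    if species.subclass == "TAG":
        tag_size = classify_tag_size(species.total_carbons)
        detailed = f"{tag_size} TAG"
    else:
        tag_size = "not-applicable"
        detailed = species.subclass
    return LipidAnnotation(
        species=species.name,
        subclass=species.subclass,
        total_carbons=species.total_carbons,
        total_double_bonds=species.total_double_bonds,
        tag_size=tag_size,
        saturation_set=saturation,
        omega_set=omega,
        parity_set=parity,
        fa_set=frozenset(fas),
        subclass_detailed=detailed,
    )


#: The five annotation families used by the enrichment layer.
FAMILIES = ("OddEven_All", "Omega_All", "Saturation_All",
            "Lipid_Class_Detailed_Special", "FA_All")


def build_annotation_catalog(
    names: Iterable[str],
    omega_lookup: Mapping[FattyAcyl, str] | None = None,
) -> pd.DataFrame:
    """Build the tidy annotation catalog for a set of species names.

    Returns a DataFrame with columns ``species``, ``category_family``,
    ``category`` — one row per (species, category) membership, covering the
    five families: chain parity, omega class, saturation, detailed subclass
    (ether-PE and small/large TAG kept distinct) and constituent FA.
    """
    if omega_lookup is None:
        omega_lookup = load_omega_lookup()
    rows = []
    for name in names:
        ann = annotate(parse_lipid_name(name), omega_lookup)
        for cat in sorted(ann.parity_set):
            rows.append((ann.species, "OddEven_All", cat))
        for cat in sorted(ann.omega_set):
            if cat != "unknown":
                rows.append((ann.species, "Omega_All", cat))
        for cat in sorted(ann.saturation_set):
            rows.append((ann.species, "Saturation_All", cat))
        rows.append((ann.species, "Lipid_Class_Detailed_Special",
                     ann.subclass_detailed))
        for fa in sorted(ann.fa_set):
            rows.append((ann.species, "FA_All", f"FA({fa})"))
    return pd.DataFrame(rows, columns=["species", "category_family", "category"])
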