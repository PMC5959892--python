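"""In-silico negative-mode lipid ion database and m/z annotation.

Builds candidate glycerophospholipid (PA, PE, including ether- and
plasmalogen-linked variants) and free fatty acid ions from elemental
composition rules, computes monoisotopic ion masses for the adducts seen
in diathermy-aerosol spectra ([M-H]-, [M-NH3]-, [M+Cl]-), and matches
observed m/z bins within a tolerance (default +/- 0.1).

Composition rules (c = total acyl carbons, d = total double bonds):
  diacyl PA(c:d)  = C(c+3)  H(2c+5-2d)   O8 P
  diacyl PE(c:d)  = C(c+5)  H(2c+10-2d)  N O8 P
  FA(c:d)         = C(c)    H(2c-2d)     O2
  ether (O-)      = diacyl - O + 2H
  plasmalogen (P-)(c:d) shares the formula of ether O-(c:d+1)
Only even total carbon counts are enumerated, as odd acyl chains are rare
in mammalian tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: monoisotopic atomic masses (Da)
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376151,
    "Cl": 34.96885271,
}
PROTON_MASS = 1.00727646    # H minus the electron
ELECTRON_MASS = 0.00054858
NH3_MASS = MONOISOTOPIC["N"] + 3 * MONOISOTOPIC["H"]  # 17.02654910

ADDUCTS = ("[M-H]-", "[M-NH3]-", "[M+Cl]-")

DEFAULT_TOLERANCE = 0.1
GP_CARBON_RANGE = (24, 44)
FA_CARBON_RANGE = (12, 26)
DOUBLE_BOND_RANGE = (0, 6)


@dataclass(frozen=True)
class Formula:
    """Elemental formula as atom counts; all counts non-negative."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    P: int = 0
    Cl: int = 0

    def __post_init__(self) -> None:
        for el in ("C", "H", "N", "O", "P", "Cl"):
            if getattr(self, el) < 0:
                raise ValueError(f"invalid species: negative {el} count")

    @property
    def monoisotopic_mass(self) -> float:
        return sum(getattr(self, el) * m for el, m in MONOISOTOPIC.items())

    def __str__(self) -> str:
        parts = []
        for el in ("C", "H", "N", "O", "P", "Cl"):
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species on the headgroup/carbons/double-bond/linkage grid."""

    headgroup: str       # PA | PE | FA
    carbons: int         # total acyl carbons, even
    double_bonds: int
    linkage: str         # acyl | ether | plasmalogen
    formula: Formula

    @property
    def name(self) -> str:
        prefix = {"acyl": "", "ether": "O-", "plasmalogen": "P-"}[self.linkage]
        return f"{self.headgroup}({prefix}{self.carbons}:{self.double_bonds})"


@dataclass(frozen=True)
class AdductIon:
    species: LipidSpecies
    adduct: str
    mz: float


@dataclass
class AnnotationMatch:
    """Candidate ions within tolerance of a query m/z, nearest first."""

    query_mz: float
    tolerance: float
    candidates: list[AdductIon] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)

    def names(self) -> list[str]:
        return [f"{ion.species.name} {ion.adduct}" for ion in self.candidates]


def species_formula(headgroup: str, carbons: int, double_bonds: int,
                    linkage: str = "acyl") -> Formula:
    """Elemental formula for a lipid species from the composition rules."""
    if carbons % 2 != 0:
        raise ValueError("even-chain species only: carbons must be even")
    if carbons <= 0 or double_bonds < 0:
        raise ValueError("carbons must be positive and double_bonds non-negative")
    if headgroup == "FA":
        if linkage != "acyl":
            raise ValueError("fatty acids have no ether/plasmalogen variant here")
        return Formula(C=carbons, H=2 * carbons - 2 * double_bonds, O=2)
    if headgroup not in ("PA", "PE"):
        raise ValueError(f"unknown headgroup {headgroup!r}")

    if linkage == "plasmalogen":
        # vinyl-ether linkage: same formula as the ether species with one more DB
        return species_formula(headgroup, carbons, double_bonds + 1, "ether")

    if headgroup == "PA":
        f = Formula(C=carbons + 3, H=2 * carbons + 5 - 2 * double_bonds, O=8, P=1)
    else:  # PE
        f = Formula(C=carbons + 5, H=2 * carbons + 10 - 2 * double_bonds, N=1, O=8, P=1)
    if linkage == "ether":
        f = Formula(C=f.C, H=f.H + 2, N=f.N, O=f.O - 1, P=f.P)
    elif linkage != "acyl":
        raise ValueError(f"unknown linkage {linkage!r}")
    return f


def adduct_mz(formula: Formula, adduct: str) -> float:
    """Theoretical m/z of a singly charged negative ion of the neutral M."""
    M = formula.monoisotopic_mass
    if adduct == "[M-H]-":
        return M - PROTON_MASS
    if adduct == "[M-NH3]-":
        if formula.N == 0:
            raise ValueError("[M-NH3]- requires a nitrogen-containing species")
        return M - NH3_MASS - PROTON_MASS
    if adduct == "[M+Cl]-":
        return M + MONOISOTOPIC["Cl"] + ELECTRON_MASS
    raise ValueError(f"unknown adduct {adduct!r}")


def build_database(
    headgroups: tuple = ("PA", "PE", "FA"),
    gp_carbons: tuple[int, int] = GP_CARBON_RANGE,
    fa_carbons: tuple[int, int] = FA_CARBON_RANGE,
    double_bonds: tuple[int, int] = DOUBLE_BOND_RANGE,
    linkages: tuple = ("acyl", "ether", "plasmalogen"),
    adducts: tuple = ADDUCTS,
) -> list[AdductIon]:
    """Enumerate the candidate ion grid (even chains only)."""
    ions = []
    for head in headgroups:
        lo, hi = fa_carbons if head == "FA" else gp_carbons
        links = ("acyl",) if head == "FA" else linkages
        for c in range(lo, hi + 1, 2):
            for d in range(double_bonds[0], double_bonds[1] + 1):
                for link in links:
                    try:
                        f = species_formula(head, c, d, link)
                    except ValueError:
                        continue
                    sp = LipidSpecies(head, c, d, link, f)
                    for adduct in adducts:
                        if adduct == "[M-NH3]-" and f.N == 0:
                            continue
                        ions.append(AdductIon(sp, adduct, adduct_mz(f, adduct)))
    return ions


def annotate(query_mz: float, tolerance: float = DEFAULT_TOLERANCE,
             database: list[AdductIon] | None = None) -> AnnotationMatch:
    """All database ions within ``|theoretical - query| <= tolerance``.

    An empty candidate list is a valid result. Candidates are sorted by
    absolute mass error, nearest first.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if database is None:
        database = build_database()
    scored = [(abs(ion.mz - query_mz), ion) for ion in database
              if abs(ion.mz - query_mz) <= tolerance]
    scored.sort(key=lambda pair: pair[0])
    return AnnotationMatch(
        query_mz=float(query_mz), tolerance=float(tolerance),
        candidates=[ion for _, ion in scored], errors=[err for err, _ in scored],
    )


def database_frame(database: list[AdductIon] | None = None):
    """Database as a DataFrame for CSV export."""
    import pandas as pd

    database = build_database() if database is None else database
    return pd.DataFrame({
        "species": [ion.species.name for ion in database],
        "headgroup": [ion.species.headgroup for ion in database],
        "carbons": [ion.species.carbons for ion in database],
        "double_bonds": [ion.species.double_bonds for ion in database],
        "linkage": [ion.species.linkage for ion in database],
        "formula": [str(ion.species.formula) for ion in database],
        "adduct": [ion.adduct for ion in database],
        "mz": [round(ion.mz, 4) for ion in database],
    })
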