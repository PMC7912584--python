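"""Species thermochemistry tables and complexation reaction definitions.

A species table is a CSV/TSV/JSON listing of solution-phase species with
their standard Gibbs free energies (internally always kcal/mol; hartree
accepted on input). Reactions encode the chelation equilibria

    x L^(m-1) + [M(H2O)_c]^q+  <=>  [M(L)_x(H2O)_n]^(q-x)+ + (c-n) H2O + x*m H+

with c = 4 for square-planar Cu(II) and c = 6 for octahedral Fe(III);
m is the number of protons the ligand sheds on entering the complex
(0 for an already-anionic ligand read in its chelating form).
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd

from .constants import HARTREE_TO_KCAL
from .errors import (
    BalanceError,
    ConfigError,
    DuplicateLabelError,
    SchemaError,
    SpeciesLookupError,
    TableParseError,
)

ROLES = frozenset(
    {
        "metal_aqua",
        "ligand",
        "complex",
        "reduced_complex",
        "water",
        "oxidant",
        "oxidized_product",
        "proton",
    }
)

METALS = frozenset({"Cu", "Fe", "none"})

#: Coordination number of the hydrated ion, by metal.
COORDINATION = {"Cu": 4, "Fe": 6}

#: Formal charge of the oxidized hydrated ion, by metal.
METAL_CHARGE = {"Cu": 2, "Fe": 3}

REQUIRED_COLUMNS = ("label", "role", "charge", "unpaired_electrons", "g_standard")
OPTIONAL_COLUMNS = (
    "h_standard",
    "s2_before",
    "s2_after",
    "metal",
    "n_ligands",
    "stokes_radius",
)


@dataclass(frozen=True)
class SpeciesRecord:
    """One chemical species with charge, spin and standard Gibbs energy."""

    label: str
    role: str
    charge: int
    unpaired_electrons: int
    g_standard: float  # kcal/mol
    h_standard: float | None = None  # kcal/mol
    s2_before: float | None = None
    s2_after: float | None = None
    metal: str = "none"
    n_ligands: int = 0
    stokes_radius: float | None = None  # Angstrom

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for species {self.label!r}")
        if self.metal not in METALS:
            raise SchemaError(f"unknown metal {self.metal!r} for species {self.label!r}")
        if self.unpaired_electrons < 0:
            raise ValueError(f"unpaired_electrons < 0 for {self.label!r}")
        if self.n_ligands < 0:
            raise ValueError(f"n_ligands < 0 for {self.label!r}")
        if not math.isfinite(self.g_standard):
            raise ValueError(f"g_standard not finite for {self.label!r}")
        if self.stokes_radius is not None and self.stokes_radius <= 0:
            raise ValueError(f"stokes_radius must be > 0 for {self.label!r}")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric complexation equilibrium.

    ``x`` is the ligand count and ``n`` the retained-water count of the
    product complex; both are optional metadata used for scheme-level
    bookkeeping during validation.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    scheme_id: str | None = None
    x: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple((str(l), int(c)) for l, c in self.reactants))
        object.__setattr__(self, "products", tuple((str(l), int(c)) for l, c in self.products))
        for label, coeff in (*self.reactants, *self.products):
            if coeff < 1:
                raise ValueError(f"coefficient for {label!r} must be >= 1, got {coeff}")

    def labels(self) -> set[str]:
        return {l for l, _ in self.reactants} | {l for l, _ in self.products}


@dataclass
class BalanceReport:
    """Outcome of checking a reaction against its species records."""

    passed: bool
    charge_reactants: int
    charge_products: int
    charge_discrepancy: int
    metal_reactants: dict[str, int]
    metal_products: dict[str, int]
    messages: list[str] = field(default_factory=list)


SpeciesMap = dict[str, SpeciesRecord]


def _species_map(species: Union[SpeciesMap, Iterable[SpeciesRecord]]) -> SpeciesMap:
    if isinstance(species, Mapping):
        return dict(species)
    return {s.label: s for s in species}


# ---------------------------------------------------------------------------
# reading

_OPTIONAL_INT = {"n_ligands"}


def _coerce_record(row: Mapping, idx, energy_factor: float) -> SpeciesRecord:
    def num(col, required=False):
        val = row.get(col)
        if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
            if required:
                raise TableParseError(f"row {idx}: missing value for {col!r}")
            return None
        try:
            return float(val)
        except (TypeError, ValueError):
            raise TableParseError(f"row {idx}: non-numeric {col!r} value {val!r}") from None

    g = num("g_standard", required=True) * energy_factor
    h = num("h_standard")
    if h is not None:
        h *= energy_factor
    metal = row.get("metal")
    if metal is None or (isinstance(metal, float) and math.isnan(metal)) or metal == "":
        metal = "none"
    n_lig = num("n_ligands")
    radius = num("stokes_radius")
    try:
        charge = int(num("charge", required=True))
        unpaired = int(num("unpaired_electrons", required=True))
    except TableParseError:
        raise
    return SpeciesRecord(
        label=str(row["label"]),
        role=str(row["role"]),
        charge=charge,
        unpaired_electrons=unpaired,
        g_standard=g,
        h_standard=h,
        s2_before=num("s2_before"),
        s2_after=num("s2_after"),
        metal=str(metal),
        n_ligands=int(n_lig) if n_lig is not None else 0,
        stokes_radius=radius,
    )


def read_species_table(
    source: Union[str, Path, TextIO],
    energy_unit: str = "kcal/mol",
) -> SpeciesMap:
    """Read and validate a species table (CSV, TSV or JSON list of objects).

    Hartree energies are converted to kcal/mol on input using the CODATA
    factor; everything downstream works in kcal/mol.
    """
    if energy_unit == "hartree":
        factor = HARTREE_TO_KCAL
    elif energy_unit == "kcal/mol":
        factor = 1.0
    else:
        raise ConfigError(f"unknown energy unit {energy_unit!r}")

    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()

    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        rows = json.loads(text)
        if isinstance(rows, Mapping):
            rows = [rows]
    else:
        header = stripped.splitlines()[0] if stripped else ""
        sep = "\t" if "\t" in header else ","
        df = pd.read_csv(_io.StringIO(text), sep=sep, dtype=str, skipinitialspace=True)
        rows = df.to_dict(orient="records")

    if not rows:
        raise SchemaError("species table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in rows[0]]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    out: SpeciesMap = {}
    for idx, row in enumerate(rows):
        rec = _coerce_record(row, idx, factor)
        if rec.label in out:
            raise DuplicateLabelError(f"duplicate species label {rec.label!r}")
        out[rec.label] = rec
    return out


def read_reactions(source: Union[str, Path, TextIO]) -> list[Reaction]:
    """Read reaction definitions from a JSON array."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    raw = json.loads(text)
    out = []
    for item in raw:
        out.append(
            Reaction(
                reactants=tuple((l, c) for l, c in item["reactants"]),
                products=tuple((l, c) for l, c in item["products"]),
                scheme_id=item.get("scheme_id"),
                x=item.get("x"),
                n=item.get("n"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# scheme templates

#: protons released per ligand, by scheme tag
SCHEME_PROTONS = {"5": 0, "6": 0, "7": 0, "8": 0, "9": 0, "10": 0,
                  "17": 1, "18": 2, "19": 1, "20": 2}
SCHEME_METAL = {"5": "Cu", "6": "Cu", "7": "Cu", "8": "Fe", "9": "Fe", "10": "Fe",
                "17": "Cu", "18": "Cu", "19": "Fe", "20": "Fe"}


def build_scheme_reaction(
    scheme_id: str,
    x: int,
    n: int,
    ligand_label: str,
    complex_label: str,
    metal_aqua_label: str | None = None,
    water_label: str = "H2O",
    proton_label: str = "H+",
) -> Reaction:
    """Instantiate one of the standard chelation equilibria.

    Anionic-ligand schemes (tags ``5``-``10``) release only water; the
    pH-explicit schemes (``17``-``20``) additionally release ``x*m``
    protons from a ligand read in its dominant protonation state.
    """
    scheme_id = str(scheme_id)
    if scheme_id not in SCHEME_PROTONS:
        raise ConfigError(f"unknown scheme {scheme_id!r}")
    metal = SCHEME_METAL[scheme_id]
    coord = COORDINATION[metal]
    if not (0 <= n <= coord):
        raise ConfigError(f"retained waters n={n} out of range for {metal}")
    if x < 1:
        raise ConfigError(f"ligand count x must be >= 1, got {x}")
    m = SCHEME_PROTONS[scheme_id]
    if metal_aqua_label is None:
        metal_aqua_label = f"[{metal}(H2O){coord}]{METAL_CHARGE[metal]}+"
    reactants = [(ligand_label, x), (metal_aqua_label, 1)]
    products: list[tuple[str, int]] = [(complex_label, 1)]
    released = coord - n
    if released > 0:
        products.append((water_label, released))
    if m * x > 0:
        products.append((proton_label, m * x))
    return Reaction(
        reactants=tuple(reactants),
        products=tuple(products),
        scheme_id=scheme_id,
        x=x,
        n=n,
    )


def scheme_species_charges(scheme_id: str, x: int) -> dict[str, int]:
    """Formal charges of (ligand, metal aqua, complex) under a scheme."""
    scheme_id = str(scheme_id)
    m = SCHEME_PROTONS[scheme_id]
    q = METAL_CHARGE[SCHEME_METAL[scheme_id]]
    return {"ligand": m - 1, "metal_aqua": q, "complex": q - x}


# ---------------------------------------------------------------------------
# validation


def validate_reaction(
    reaction: Reaction,
    species: Union[SpeciesMap, Iterable[SpeciesRecord]],
) -> BalanceReport:
    """Check charge balance, metal conservation and scheme bookkeeping.

    Raises :class:`SpeciesLookupError` for unresolvable labels; balance
    failures are reported, not raised, so callers can collect them.
    """
    smap = _species_map(species)
    for label in reaction.labels():
        if label not in smap:
            raise SpeciesLookupError(f"no species record for label {label!r}")

    def charge(side):
        return sum(coeff * smap[l].charge for l, coeff in side)

    def metals(side):
        counts: dict[str, int] = {}
        for l, coeff in side:
            met = smap[l].metal
            if met != "none":
                counts[met] = counts.get(met, 0) + coeff
        return counts

    q_lhs, q_rhs = charge(reaction.reactants), charge(reaction.products)
    m_lhs, m_rhs = metals(reaction.reactants), metals(reaction.products)
    messages: list[str] = []
    ok = True
    if q_lhs != q_rhs:
        ok = False
        messages.append(f"charge imbalance: reactants {q_lhs:+d} vs products {q_rhs:+d}")
    if m_lhs != m_rhs:
        ok = False
        messages.append(f"metal imbalance: reactants {m_lhs} vs products {m_rhs}")

    # scheme-level water/proton bookkeeping
    if reaction.scheme_id is not None and reaction.x is not None and reaction.n is not None:
        sid = str(reaction.scheme_id)
        if sid in SCHEME_PROTONS:
            coord = COORDINATION[SCHEME_METAL[sid]]
            expect_water = coord - reaction.n
            got_water = sum(
                c for l, c in reaction.products if smap[l].role == "water"
            )
            if got_water != expect_water:
                ok = False
                messages.append(
                    f"water release {got_water} != expected ({coord} - n) = {expect_water}"
                )
            expect_h = SCHEME_PROTONS[sid] * reaction.x
            got_h = sum(c for l, c in reaction.products if smap[l].role == "proton")
            if got_h != expect_h:
                ok = False
                messages.append(f"proton release {got_h} != expected x*m = {expect_h}")
            got_lig = sum(c for l, c in reaction.reactants if smap[l].role == "ligand")
            if got_lig != reaction.x:
                ok = False
                messages.append(f"ligand count {got_lig} != declared x = {reaction.x}")

    return BalanceReport(
        passed=ok,
        charge_reactants=q_lhs,
        charge_products=q_rhs,
        charge_discrepancy=q_rhs - q_lhs,
        metal_reactants=m_lhs,
        metal_products=m_rhs,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# result tables

#: per-field output formats matching the published table layout:
#: free energies to 1 decimal, logK to 2 decimals, equilibrium/rate
#: constants in 3-significant-figure scientific notation.
_FIELD_FORMATS = {
    "delta_g_raw": "{:.1f}",
    "ss_correction": "{:.2f}",
    "dep_penalty_total": "{:.2f}",
    "delta_g_formation": "{:.1f}",
    "logKf": "{:.2f}",
    "Kf": "{:.3g}",
    "delta_g_act": "{:.2f}",
    "k_act": "{:.3g}",
    "k_diff": "{:.3g}",
    "k_app": "{:.3g}",
    "ratio_vs_reference": "{:.3g}",
}


def _result_row(result, flatten: bool = True) -> dict:
    d = dataclasses.asdict(result)
    if flatten and isinstance(d.get("reaction"), dict):
        rxn = d.pop("reaction")
        d = {"reaction": _reaction_str(rxn), **d}
    return d


def _reaction_str(rxn: Mapping) -> str:
    def side(terms):
        return " + ".join(f"{c} {l}" if c > 1 else l for l, c in terms)

    return f"{side(rxn['reactants'])} -> {side(rxn['products'])}"


def _fmt(key, value):
    if value is None:
        return ""
    fmt = _FIELD_FORMATS.get(key)
    if fmt is not None and isinstance(value, float):
        return fmt.format(value)
    return str(value)


def write_results_table(
    results: Sequence,
    fmt: str = "tsv",
    destination: Union[str, Path, TextIO, None] = None,
) -> str:
    """Serialize result dataclasses as TSV, markdown or JSON.

    TSV/markdown apply the publication rounding; JSON keeps full
    precision and round-trips losslessly.
    """
    if results is None:
        raise ValueError("results must not be None")
    if fmt == "json":
        # nested, full-precision form; round-trips losslessly
        rows = [_result_row(r, flatten=False) for r in results]
        text = json.dumps(rows, indent=2)
        if destination is not None:
            if isinstance(destination, (str, Path)):
                Path(destination).write_text(text)
            else:
                destination.write(text)
        return text

    rows = [_result_row(r) for r in results]
    columns: list[str] = []
    for row in rows:
        for key in row:
            if key not in columns:
                columns.append(key)

    if fmt == "tsv":
        lines = ["\t".join(columns)]
        for row in rows:
            lines.append("\t".join(_fmt(c, row.get(c)) for c in columns))
        text = "\n".join(lines) + "\n"
    elif fmt == "markdown":
        lines = ["| " + " | ".join(columns) + " |",
                 "|" + "|".join(" --- " for _ in columns) + "|"]
        for row in rows:
            lines.append("| " + " | ".join(_fmt(c, row.get(c)) for c in columns) + " |")
        text = "\n".join(lines) + "\n"
    else:
        raise ConfigError(f"unknown table format {fmt!r}")

    if destination is not None:
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)
    return text


def read_results_table(source: Union[str, Path, TextIO]):
    """Reconstruct result dataclasses from the JSON table format.

    Rows with a ``reaction`` field become
    :class:`~metallokin.thermo.FormationResult`; rows with ``k_act``
    become :class:`~metallokin.et_kinetics.RateResult`.
    """
    from .et_kinetics import RateResult
    from .thermo import FormationResult

    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    rows = json.loads(text)
    out = []
    for row in rows:
        if "reaction" in row:
            rxn = row["reaction"]
            row = dict(row)
            row["reaction"] = Reaction(
                reactants=tuple(tuple(t) for t in rxn["reactants"]),
                products=tuple(tuple(t) for t in rxn["products"]),
                scheme_id=rxn.get("scheme_id"),
                x=rxn.get("x"),
                n=rxn.get("n"),
            )
            out.append(FormationResult(**row))
        else:
            out.append(RateResult(**row))
    return out
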