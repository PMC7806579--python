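"""Elemental formulae and exact-mass arithmetic for singly charged ESI ion species.

Everything downstream of this module reasons about ions as *symbolic* species —
a multimer order ``n`` plus a multiset of small composition changes (metal/proton
replacements, neutral adducts, neutral losses) applied to the protonated frame
``[nM+H]+``.  Keeping species symbolic (rather than as bare mass deltas) lets the
annotator label edges, merge equivalent derivations, and print canonical bracket
notation such as ``[2M+Na]+`` or ``[3M+Na+Ca-2H]+``.

Masses are monoisotopic throughout; only net charge +1 is supported, which is the
regime of small-molecule positive-mode ESI this package targets.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_SPACING",
    "Formula",
    "parse_formula",
    "monoisotopic_mass",
    "BaseDelta",
    "DELTA_REGISTRY",
    "DEFAULT_DELTA_NAMES",
    "IonSpecies",
    "AnnotationDelta",
    "ion_mz",
    "species_delta",
    "expand_species_closure",
]

#: Monoisotopic masses of the elements accepted in formulae (Da, CODATA/NIST).
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "Al": 26.98153863,
    "Si": 27.97692653,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Mn": 54.9380451,
    "Fe": 55.9349375,
    "Co": 58.933195,
    "Ni": 57.9353429,
    "Cu": 62.9295975,
    "Zn": 63.9291422,
    "As": 74.9215965,
    "Se": 79.9165213,
    "Br": 78.9183371,
    "I": 126.904473,
    "Li": 7.01600455,
    "B": 11.0093054,
}

ELECTRON_MASS = 0.000549
#: Mass of the charge-carrying proton (H minus one electron), Da.
PROTON_MASS = ELEMENT_MASSES["H"] - ELECTRON_MASS
#: 13C - 12C spacing used for deisotoping singly charged envelopes, Da.
C13_SPACING = 1.003355


class FormulaError(ValueError):
    """Raised for malformed or unknown-element formula strings."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d{0,4})")


@dataclass(frozen=True)
class Formula:
    """An elemental composition, e.g. ``C5H9NO2`` for l-proline."""

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.element_counts.items():
            if sym not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if n <= 0:
                raise FormulaError(f"non-positive count for element {sym!r}")
            clean[sym] = int(n)
        object.__setattr__(self, "element_counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        return parse_formula(text)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(ELEMENT_MASSES[s] * n for s, n in self.element_counts.items())

    def __add__(self, other: "Formula") -> "Formula":
        merged = Counter(self.element_counts)
        merged.update(other.element_counts)
        return Formula(dict(merged))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        counts = dict(self.element_counts)
        order = [s for s in ("C", "H") if s in counts]
        order += sorted(s for s in counts if s not in ("C", "H"))
        return "".join(f"{s}{counts[s] if counts[s] != 1 else ''}" for s in order)


def parse_formula(text: str) -> Formula:
    """Parse an elemental formula string such as ``"C5H9NO2"``.

    Counts of 1 may be omitted.  No parentheses, isotopes or charge signs are
    accepted; unknown element symbols raise :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Counter[str] = Counter()
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, num = m.groups()
        if sym not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] += int(num) if num else 1
        pos = m.end()
    return Formula(dict(counts))


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic mass of a neutral formula, Da."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f.mass


# ---------------------------------------------------------------------------
# Base deltas and ion species
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseDelta:
    """One elementary composition change applied to a protonated frame.

    ``composition`` maps element symbol to a signed atom count; ``max_mult`` is
    the default cap on how many times the change may be stacked in one species
    (metal/proton replacements stack with the number of labile protons, neutral
    ammonia gains/losses essentially do not).
    """

    name: str
    composition: Mapping[str, int]
    max_mult: int = 1

    @property
    def mass(self) -> float:
        return sum(ELEMENT_MASSES[s] * n for s, n in self.composition.items())


DELTA_REGISTRY: dict[str, BaseDelta] = {
    d.name: d
    for d in (
        BaseDelta("Na_adduct", {"Na": 1, "H": -1}, max_mult=3),   # Na-H = 21.9819
        BaseDelta("K_adduct", {"K": 1, "H": -1}, max_mult=3),     # K-H  = 37.9559
        BaseDelta("Ca_adduct", {"Ca": 1, "H": -2}, max_mult=2),   # Ca-2H = 37.9469
        BaseDelta("NH3_adduct", {"N": 1, "H": 3}, max_mult=1),    # +NH3 = 17.0265
        BaseDelta("H2O_loss", {"H": -2, "O": -1}, max_mult=2),    # -H2O = -18.0106
        BaseDelta("NH3_loss", {"N": -1, "H": -3}, max_mult=1),    # -NH3 = -17.0265
    )
}

#: Default positive-mode annotation set: ammonium, sodium and potassium adducts
#: plus ammonia and water losses.
DEFAULT_DELTA_NAMES: tuple[str, ...] = (
    "NH3_adduct",
    "Na_adduct",
    "K_adduct",
    "H2O_loss",
    "NH3_loss",
)


class ChargeError(ValueError):
    """Raised when an operation requires net charge +1 and gets something else."""


class LabelError(ValueError):
    """Raised for ion-species labels that cannot be parsed."""


def _resolve_delta(d: "BaseDelta | str") -> BaseDelta:
    if isinstance(d, BaseDelta):
        return d
    try:
        return DELTA_REGISTRY[d]
    except KeyError:
        raise KeyError(f"unknown base delta {d!r}; known: {sorted(DELTA_REGISTRY)}") from None


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ion species ``[nM ± ...]+``.

    The species is the protonated frame ``[nM+H]+`` with ``delta_counts`` copies
    of the named base deltas applied.  Two species with the same multimer order
    and the same net atomic composition are considered equal even if derived by
    different delta paths.
    """

    multimer_n: int = 1
    delta_counts: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.multimer_n < 1:
            raise ChargeError("multimer order must be a positive integer")
        canon = tuple(sorted((n, c) for n, c in self.delta_counts if c))
        for name, c in canon:
            _resolve_delta(name)
            if c < 0:
                raise ValueError(f"negative multiplicity for delta {name!r}")
        object.__setattr__(self, "delta_counts", canon)

    @classmethod
    def protonated(cls, n: int = 1) -> "IonSpecies":
        return cls(multimer_n=n)

    @classmethod
    def from_deltas(cls, deltas: Iterable[str], n: int = 1) -> "IonSpecies":
        counts = Counter(deltas)
        return cls(multimer_n=n, delta_counts=tuple(counts.items()))

    # -- mass arithmetic ----------------------------------------------------

    @property
    def charge(self) -> int:
        return 1

    @property
    def composition(self) -> Counter:
        """Signed atom changes relative to the neutral ``nM``, charge H included."""
        comp: Counter[str] = Counter({"H": 1})
        for name, c in self.delta_counts:
            for sym, k in _resolve_delta(name).composition.items():
                comp[sym] += k * c
        return Counter({s: k for s, k in comp.items() if k})

    @property
    def mass_offset(self) -> float:
        """m/z offset added to ``n * M`` (electron already accounted for)."""
        return PROTON_MASS + sum(
            _resolve_delta(name).mass * c for name, c in self.delta_counts
        )

    def ion_mz(self, neutral_mass: float) -> float:
        if neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        return self.multimer_n * neutral_mass + self.mass_offset

    @property
    def depth(self) -> int:
        return sum(c for _, c in self.delta_counts)

    def _counts(self) -> Counter:
        return Counter(dict(self.delta_counts))

    # Composition-level identity: two delta paths with the same net atoms merge.
    def _key(self) -> tuple:
        comp = Counter({"H": 1})
        for name, c in self.delta_counts:
            for sym, k in _resolve_delta(name).composition.items():
                comp[sym] += k * c
        return (self.multimer_n, tuple(sorted((s, k) for s, k in comp.items() if k)))

    # -- canonical label ----------------------------------------------------

    @property
    def label(self) -> str:
        c = self._counts()
        a, b, ca = c["Na_adduct"], c["K_adduct"], c["Ca_adduct"]
        g, w, l = c["NH3_adduct"], c["H2O_loss"], c["NH3_loss"]
        h = 1 - a - b - 2 * ca
        nh4 = 0
        if g and h >= 1:  # one ammonia gain plus the charge proton prints as NH4
            nh4, g, h = 1, g - 1, h - 1
        parts: list[str] = []

        def add(sign: str, count: int, sym: str) -> None:
            if count:
                parts.append(f"{sign}{count if count > 1 else ''}{sym}")

        if h > 0:
            add("+", h, "H")
        add("+", nh4, "NH4")
        add("+", a, "Na")
        add("+", b, "K")
        add("+", ca, "Ca")
        add("+", g, "NH3")
        if h < 0:
            add("-", -h, "H")
        add("-", l, "NH3")
        add("-", w, "H2O")
        nm = f"{self.multimer_n}M" if self.multimer_n > 1 else "M"
        return f"[{nm}{''.join(parts)}]+"

    _LABEL_RE = re.compile(r"^\[(\d*)M((?:[+-]\d*[A-Za-z0-9]+)*)\]\+$")
    _TOKEN_RE = re.compile(r"([+-])(\d*)(NH4|NH3|H2O|Na|K|Ca|H)")

    @classmethod
    def parse_label(cls, label: str) -> "IonSpecies":
        m = cls._LABEL_RE.match(label.strip())
        if not m:
            raise LabelError(f"cannot parse ion species label {label!r}")
        n = int(m.group(1)) if m.group(1) else 1
        body = m.group(2)
        tok_counts: Counter[tuple[str, str]] = Counter()
        pos = 0
        for t in cls._TOKEN_RE.finditer(body):
            if t.start() != pos:
                raise LabelError(f"cannot parse ion species label {label!r}")
            sign, num, sym = t.groups()
            tok_counts[(sign, sym)] += int(num) if num else 1
            pos = t.end()
        if pos != len(body):
            raise LabelError(f"cannot parse ion species label {label!r}")
        deltas: Counter[str] = Counter()
        h = tok_counts[("+", "H")] - tok_counts[("-", "H")]
        deltas["Na_adduct"] = tok_counts[("+", "Na")]
        deltas["K_adduct"] = tok_counts[("+", "K")]
        deltas["Ca_adduct"] = tok_counts[("+", "Ca")]
        deltas["NH3_adduct"] = tok_counts[("+", "NH3")] + tok_counts[("+", "NH4")]
        deltas["H2O_loss"] = tok_counts[("-", "H2O")]
        deltas["NH3_loss"] = tok_counts[("-", "NH3")]
        if tok_counts[("+", "NH4")]:
            h += tok_counts[("+", "NH4")]  # NH4 carries the charge proton
        expected_h = 1 - deltas["Na_adduct"] - deltas["K_adduct"] - 2 * deltas["Ca_adduct"]
        if h != expected_h:
            raise LabelError(
                f"label {label!r} has inconsistent hydrogen bookkeeping "
                f"(saw net {h:+d}H, expected {expected_h:+d}H)"
            )
        if tok_counts[("-", "Na")] or tok_counts[("-", "K")] or tok_counts[("-", "Ca")] \
                or tok_counts[("-", "NH4")] or tok_counts[("+", "H2O")]:
            raise LabelError(f"unsupported token in label {label!r}")
        return cls(multimer_n=n, delta_counts=tuple(deltas.items()))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class AnnotationDelta:
    """A directed relation between two ion species of the same multimer order."""

    from_species: IonSpecies
    to_species: IonSpecies
    delta_mass: float
    directed: bool = True

    def __post_init__(self) -> None:
        expected = self.to_species.mass_offset - self.from_species.mass_offset
        if abs(expected - self.delta_mass) > 1e-6:
            raise ValueError(
                f"delta_mass {self.delta_mass:.6f} inconsistent with species "
                f"offsets ({expected:.6f})"
            )


def ion_mz(neutral_mass: float, species: IonSpecies) -> float:
    """m/z of ``species`` for an analyte of the given neutral monoisotopic mass."""
    if species.charge != 1:
        raise ChargeError("only net charge +1 species are supported")
    return species.ion_mz(neutral_mass)


def species_delta(a: IonSpecies, b: IonSpecies) -> float:
    """Signed mass difference ``b - a`` for species on the same multimer frame.

    Relations across multimer orders depend on the neutral mass itself and are
    the graph builder's job, so they are rejected here.
    """
    if a.multimer_n != b.multimer_n:
        raise ValueError(
            "species_delta is undefined across multimer orders; "
            "use the graph builder's multimer matching instead"
        )
    return b.mass_offset - a.mass_offset


#: Default combination depth.  Every combination species observed in routine
#: positive-mode runs is a two-delta stack ([M+Na+K-H]+, [M+2Na-H]+,
#: [M+Na+NH3]+, [M+H-NH3-H2O]+, [M+H-2H2O]+, [M+K-H2O]+); deeper stacks add
#: mostly spurious relations (e.g. K-H2O-NH3 = 2.9188 Da tunnels between
#: unrelated co-eluting analytes) and can be enabled per run when hunting
#: extended replacement series.
DEFAULT_MAX_DEPTH = 2


def expand_species_closure(
    base_set: Sequence[BaseDelta | str] = DEFAULT_DELTA_NAMES,
    max_depth: int = DEFAULT_MAX_DEPTH,
    multimers: Sequence[int] = (1, 2, 3),
    max_mult: Mapping[str, int] | None = None,
) -> list[IonSpecies]:
    """All distinct species reachable from ``[nM+H]+`` by stacking base deltas.

    Combinations of at most ``max_depth`` deltas are formed, with each delta
    additionally capped at its own multiplicity (``BaseDelta.max_mult``, which
    ``max_mult`` may override by name).  Species whose delta paths cancel to the
    same net composition are merged, keeping the shortest derivation, so e.g. an
    ammonia gain followed by an ammonia loss collapses onto ``[M+H]+``.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    deltas = [_resolve_delta(d) for d in base_set]
    caps = {d.name: d.max_mult for d in deltas}
    if max_mult:
        caps.update(max_mult)

    seen: dict[tuple, IonSpecies] = {}
    out: list[IonSpecies] = []
    names = [d.name for d in deltas]
    # enumerate multiplicity vectors by total depth so shortest derivations win
    ranges = [range(min(caps[n], max_depth) + 1) for n in names]
    combos = sorted(itertools.product(*ranges), key=sum)
    for n in multimers:
        if n < 1:
            raise ValueError("multimer orders must be positive")
        for combo in combos:
            if sum(combo) > max_depth:
                continue
            sp = IonSpecies(
                multimer_n=n,
                delta_counts=tuple((nm, c) for nm, c in zip(names, combo) if c),
            )
            key = sp._key()
            if key not in seen:
                seen[key] = sp
                out.append(sp)
    out.sort(key=lambda s: (s.multimer_n, s.mass_offset))
    return out
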