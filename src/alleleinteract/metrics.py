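"""Allele-interaction calculus for a biallelic locus.

A biallelic locus has five genotypic values: the two homozygotes ``x11`` and
``x22``, the heterozygote ``x12``, and the two hemizygotes ``h1`` and ``h2``
(genotypes with one allele knocked out).  The *allele interaction value* of
genotype ij,

    delta_ij = x_ij - (h_i + h_j),

measures the functional dependency between the two gene copies present in that
genotype: delta_ij = 0 means the biallelic phenotype is exactly the sum of the
two monoallelic phenotypes (additive allele action), while positive/negative
values mean the copies reinforce/repress each other.

The classical additive and dominance genotypic values are

    a = (x22 - x11) / 2,        d = x12 - (x11 + x22) / 2,

with alleles labelled so that x11 <= x22.  The dominance value is a linear
combination of the three interaction values,

    d = delta_12 - (delta_11 + delta_22) / 2,

so the sign of dominance is determined by the signs *and magnitudes* of all
three allele interactions, not by the heterozygote interaction alone.  Calling
each delta's sign (with a relative tolerance band around zero) yields a *sign
motif*; after collapsing allele-relabelling symmetry (which reverses the
triplet) there are exactly 18 distinct motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "MINUS",
    "ZERO",
    "PLUS",
    "PhenotypeQuintet",
    "DeltaTriplet",
    "SignMotif",
    "GeneAction",
    "InvalidQuintetError",
    "DegenerateLocusError",
    "allele_interaction",
    "gene_action",
    "dominance_from_deltas",
    "call_signs",
    "canonical_motif",
    "enumerate_motifs",
    "dominance_sign_set",
    "NEGATIVE_OVERDOMINANCE",
    "NEGATIVE_DOMINANCE",
    "ADDITIVE",
    "POSITIVE_DOMINANCE",
    "POSITIVE_OVERDOMINANCE",
    "OVERDOMINANT_CLASSES",
]

MINUS, ZERO, PLUS = -1, 0, 1

#: canonical ordering of sign symbols used for motif canonicalization:
#: zero < plus < minus
_RANK = {ZERO: 0, PLUS: 1, MINUS: 2}
_GLYPH = {MINUS: "-", ZERO: "0", PLUS: "+"}
# accept ASCII hyphen, unicode minus and en-dash on input
_FROM_GLYPH = {"-": MINUS, "−": MINUS, "–": MINUS, "0": ZERO, "+": PLUS}

NEGATIVE_OVERDOMINANCE = "negative_overdominance"
NEGATIVE_DOMINANCE = "negative_dominance"
ADDITIVE = "additive"
POSITIVE_DOMINANCE = "positive_dominance"
POSITIVE_OVERDOMINANCE = "positive_overdominance"
OVERDOMINANT_CLASSES = frozenset({NEGATIVE_OVERDOMINANCE, POSITIVE_OVERDOMINANCE})
DOMINANCE_CLASSES = (
    NEGATIVE_OVERDOMINANCE,
    NEGATIVE_DOMINANCE,
    ADDITIVE,
    POSITIVE_DOMINANCE,
    POSITIVE_OVERDOMINANCE,
)


class InvalidQuintetError(ValueError):
    """Raised when a phenotype quintet contains non-finite or negative values."""


class DegenerateLocusError(ValueError):
    """Raised when a zero phenotype makes a relative tolerance band undefined."""


@dataclass(frozen=True)
class PhenotypeQuintet:
    """Five genotypic values of one biallelic locus.

    Values are equilibrium expression levels (concentration units, >= 0).
    ``oriented()`` applies the canonical allele labelling x11 <= x22; the
    relabelling swaps (x11, h1) with (x22, h2) jointly.
    """

    x11: float
    x12: float
    x22: float
    h1: float
    h2: float

    def __post_init__(self) -> None:
        for name in ("x11", "x12", "x22", "h1", "h2"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise InvalidQuintetError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise InvalidQuintetError(f"{name} must be >= 0, got {v!r}")

    def swapped(self) -> "PhenotypeQuintet":
        """Quintet with allele labels exchanged."""
        return PhenotypeQuintet(self.x22, self.x12, self.x11, self.h2, self.h1)

    @property
    def is_oriented(self) -> bool:
        if self.x11 != self.x22:
            return self.x11 < self.x22
        return self.h1 <= self.h2  # tie broken on hemizygotes, then input order

    def oriented(self) -> "PhenotypeQuintet":
        return self if self.is_oriented else self.swapped()

    def values(self) -> tuple[float, float, float, float, float]:
        return (self.x11, self.x12, self.x22, self.h1, self.h2)


@dataclass(frozen=True)
class DeltaTriplet:
    """Allele interaction values (delta_11, delta_12, delta_22) of one locus."""

    d11: float
    d12: float
    d22: float

    def __post_init__(self) -> None:
        for name in ("d11", "d12", "d22"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidQuintetError(f"{name} must be finite")

    def values(self) -> tuple[float, float, float]:
        return (self.d11, self.d12, self.d22)


@dataclass(frozen=True)
class SignMotif:
    """Ordered triplet of called signs (s11, s12, s22), each in {-1, 0, +1}."""

    s11: int
    s12: int
    s22: int

    def __post_init__(self) -> None:
        for name in ("s11", "s12", "s22"):
            if getattr(self, name) not in (-1, 0, 1):
                raise ValueError(f"{name} must be -1, 0 or +1")

    def signs(self) -> tuple[int, int, int]:
        return (self.s11, self.s12, self.s22)

    def reverse(self) -> "SignMotif":
        """Motif under allele relabelling, which reverses the triplet."""
        return SignMotif(self.s22, self.s12, self.s11)

    def _key(self) -> tuple[int, int, int]:
        return tuple(_RANK[s] for s in self.signs())  # type: ignore[return-value]

    def canonical(self) -> "SignMotif":
        """Lexicographic minimum of the motif and its reversal.

        The symbol order is zero < plus < minus, which reproduces the
        conventional printed orientation of every motif (e.g. [0 0 +] rather
        than [+ 0 0], and [+ 0 -] rather than [- 0 +]).
        """
        rev = self.reverse()
        return self if self._key() <= rev._key() else rev

    @property
    def is_canonical(self) -> bool:
        return self._key() <= self.reverse()._key()

    @property
    def token(self) -> str:
        """Compact serialization, e.g. ``"0,0,-"``."""
        return ",".join(_GLYPH[s] for s in self.signs())

    def __str__(self) -> str:
        return "[" + " ".join(_GLYPH[s] for s in self.signs()) + "]"

    @classmethod
    def from_token(cls, token: str) -> "SignMotif":
        """Parse ``"0,0,-"`` or ``"[0 0 -]"`` style strings."""
        stripped = token.strip().strip("[]")
        parts = stripped.replace(",", " ").split()
        if len(parts) != 3:
            raise ValueError(f"cannot parse sign motif from {token!r}")
        try:
            return cls(*(_FROM_GLYPH[p] for p in parts))
        except KeyError as exc:
            raise ValueError(f"bad sign symbol in {token!r}") from exc


@dataclass(frozen=True)
class GeneAction:
    """Classical gene action of one locus (oriented so that a >= 0).

    ``d_scaled`` is d/a; it is reported as NaN with ``d_scaled_defined=False``
    when the additive value is too small relative to the homozygote mean for
    the ratio to be meaningful.
    """

    a: float
    d: float
    d_scaled: float
    d_scaled_defined: bool
    dominance_class: str


def allele_interaction(q: PhenotypeQuintet) -> DeltaTriplet:
    """Allele interaction values of a quintet.

    delta_11 = x11 - 2*h1, delta_12 = x12 - (h1 + h2), delta_22 = x22 - 2*h2.
    """
    return DeltaTriplet(
        q.x11 - 2.0 * q.h1,
        q.x12 - (q.h1 + q.h2),
        q.x22 - 2.0 * q.h2,
    )


def dominance_from_deltas(t: DeltaTriplet) -> float:
    """Dominance value from the interaction triplet: d12 - (d11 + d22)/2."""
    return t.d12 - 0.5 * (t.d11 + t.d22)


def gene_action(q: PhenotypeQuintet, tol: float = 0.05) -> GeneAction:
    """Classical additive/dominance decomposition with zero-calling.

    The quintet is first put in canonical orientation (x11 <= x22).  The
    dominance value is set to zero when the heterozygote differs from the
    homozygote mean m = (x11 + x22)/2 by less than ``tol * m`` (one-sided
    relative difference, strict ``<``).  The dominance class is overdominant
    iff the (zero-called) d satisfies |d| > a.

    ``tol=0`` gives the exact calculus used in algebraic identities.
    """
    if not 0.0 <= tol < 1.0:
        raise ValueError("tol must be in [0, 1)")
    q = q.oriented()
    m = 0.5 * (q.x11 + q.x22)
    if m == 0.0:
        raise DegenerateLocusError("both homozygote phenotypes are zero")
    a = 0.5 * (q.x22 - q.x11)
    d_raw = q.x12 - m
    d = 0.0 if abs(d_raw) < tol * m else d_raw
    defined = a > 0.0 and a >= tol * m
    d_scaled = d / a if defined else math.nan
    if d == 0.0:
        cls = ADDITIVE
    elif d > 0.0:
        cls = POSITIVE_OVERDOMINANCE if d > a else POSITIVE_DOMINANCE
    else:
        cls = NEGATIVE_OVERDOMINANCE if -d > a else NEGATIVE_DOMINANCE
    return GeneAction(a=a, d=d, d_scaled=d_scaled, d_scaled_defined=defined, dominance_class=cls)


def call_signs(q: PhenotypeQuintet, tol: float = 0.05) -> SignMotif:
    """Tolerance-called sign motif of a quintet.

    Each delta is called zero when the corresponding hemizygote sum differs
    from the biallelic value by less than ``tol`` times the biallelic value;
    otherwise the sign of delta is reported.  The quintet is put in canonical
    orientation first; the returned motif is *not* canonicalized further, so
    it reflects the oriented quintet as observed.
    """
    if not 0.0 <= tol < 1.0:
        raise ValueError("tol must be in [0, 1)")
    q = q.oriented()
    signs = []
    for biallelic, mono_sum in (
        (q.x11, 2.0 * q.h1),
        (q.x12, q.h1 + q.h2),
        (q.x22, 2.0 * q.h2),
    ):
        if biallelic == 0.0:
            raise DegenerateLocusError("biallelic phenotype is zero; relative zero-call undefined")
        if abs(mono_sum - biallelic) < tol * biallelic:
            signs.append(ZERO)
        else:
            delta = biallelic - mono_sum
            signs.append(PLUS if delta > 0 else (MINUS if delta < 0 else ZERO))
    return SignMotif(*signs)


def canonical_motif(m: SignMotif) -> SignMotif:
    """Canonical representative of a motif under allele relabelling."""
    return m.canonical()


def _all_sign_triplets() -> Iterator[SignMotif]:
    for s11 in (ZERO, PLUS, MINUS):
        for s12 in (ZERO, PLUS, MINUS):
            for s22 in (ZERO, PLUS, MINUS):
                yield SignMotif(s11, s12, s22)


def enumerate_motifs() -> list[SignMotif]:
    """All 18 canonical sign motifs.

    The 27 raw sign triplets collapse to 18 orbits under triplet reversal.
    Motifs whose dominance sign is uniquely determined come first (grouped by
    that sign: zero, minus, plus), followed by the magnitude-dependent ones;
    within each group motifs are in canonical lexicographic order.
    """
    canon = sorted({m.canonical() for m in _all_sign_triplets()}, key=SignMotif._key)

    def group(m: SignMotif) -> int:
        ds = dominance_sign_set(m)
        if len(ds) > 1:
            return 3
        return {ZERO: 0, MINUS: 1, PLUS: 2}[next(iter(ds))]

    return sorted(canon, key=lambda m: (group(m), m._key()))


def dominance_sign_set(m: SignMotif) -> frozenset[int]:
    """Achievable signs of the dominance value for a given sign motif.

    Over all assignments of strictly positive magnitudes to the nonzero
    entries of the motif, d = delta12 - (delta11 + delta22)/2 can take:

    * a positive value iff s12 = + or one of the homozygote signs is -,
    * a negative value iff s12 = - or one of the homozygote signs is +,
    * zero iff the heterozygote term can be matched exactly by the homozygote
      mean: for s12 = 0 the homozygote signs must cancel (both zero or one of
      each); for s12 = +/- at least one homozygote must share that sign.
    """
    s11, s12, s22 = m.signs()
    out = set()
    if s12 == PLUS or MINUS in (s11, s22):
        out.add(PLUS)
    if s12 == MINUS or PLUS in (s11, s22):
        out.add(MINUS)
    if s12 == ZERO:
        if (s11 == ZERO and s22 == ZERO) or (s11 == -s22 and s11 != ZERO):
            out.add(ZERO)
    elif s12 == PLUS:
        if PLUS in (s11, s22):
            out.add(ZERO)
    else:
        if MINUS in (s11, s22):
            out.add(ZERO)
    return frozenset(out)
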