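"""Tab-separated quintet tables: reading, classification output, fixtures.

The primary exchange format is a UTF-8 TSV with header
``id  x11  x12  x22  h1  h2`` and one locus per row ('.' decimal separator).
Classification appends the interaction values, the called sign motif
(serialized compactly as e.g. ``0,0,-`` plus a human-readable ``[0 0 -]``
column) and the classical gene action.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import (
    PhenotypeQuintet,
    SignMotif,
    allele_interaction,
    call_signs,
    gene_action,
    enumerate_motifs,
)

__all__ = [
    "QUINTET_COLUMNS",
    "TableFormatError",
    "read_quintets",
    "write_quintets",
    "classify_quintets",
    "generate_fixtures",
    "planted_motif",
]

QUINTET_COLUMNS = ["id", "x11", "x12", "x22", "h1", "h2"]
_VALUE_COLUMNS = QUINTET_COLUMNS[1:]


class TableFormatError(ValueError):
    """A quintet table violates the expected TSV schema."""


def read_quintets(path) -> pd.DataFrame:
    """Read and validate a quintet table.

    Raises :class:`TableFormatError` naming the offending column or row for
    missing columns, non-numeric cells, negative or non-finite values, and
    duplicate ids.  Row numbers refer to data rows (header = row 0).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"{path}: not a readable TSV ({exc})") from exc
    missing = [c for c in QUINTET_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise TableFormatError(f"{path}: duplicate id {dup!r}")
    for col in _VALUE_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | ~np.isfinite(values)
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise TableFormatError(f"{path}: row {row}: column {col!r} is not a finite number")
        if (values < 0).any():
            row = int(np.flatnonzero(values < 0)[0]) + 1
            raise TableFormatError(f"{path}: row {row}: column {col!r} is negative")
        df[col] = values.astype(float)
    return df[QUINTET_COLUMNS]


def write_quintets(df: pd.DataFrame, path) -> None:
    """Write a quintet (or classification) table as TSV."""
    df.to_csv(path, sep="\t", index=False)


def classify_quintets(df: pd.DataFrame, tol: float = 0.05) -> pd.DataFrame:
    """Classify each row of a quintet table.

    Appends the allele interaction values, the canonical sign motif (compact
    and human-readable forms), and the classical gene action columns.
    """
    out = df.copy()
    extras = {k: [] for k in (
        "d11", "d12", "d22", "motif", "motif_pretty",
        "a", "d", "d_scaled", "dominance_class",
    )}
    for _, row in df.iterrows():
        q = PhenotypeQuintet(row.x11, row.x12, row.x22, row.h1, row.h2).oriented()
        deltas = allele_interaction(q)
        motif = call_signs(q, tol).canonical()
        ga = gene_action(q, tol)
        extras["d11"].append(deltas.d11)
        extras["d12"].append(deltas.d12)
        extras["d22"].append(deltas.d22)
        extras["motif"].append(motif.token)
        extras["motif_pretty"].append(str(motif))
        extras["a"].append(ga.a)
        extras["d"].append(ga.d)
        extras["d_scaled"].append(ga.d_scaled)
        extras["dominance_class"].append(ga.dominance_class)
    for k, v in extras.items():
        out[k] = v
    return out


def planted_motif(fixture_id: str) -> SignMotif:
    """Recover the motif encoded in a fixture row id (``"q003:0,0,+"``)."""
    return SignMotif.from_token(fixture_id.split(":", 1)[1])


def generate_fixtures(rng, n: int = 18) -> pd.DataFrame:
    """Quintet table with planted interaction structure covering all 18 motifs.

    Hemizygote values are drawn first; each delta is then planted with the
    motif's sign and a magnitude of roughly 20-40% of the corresponding
    hemizygote sum, and the biallelic values assembled as
    x_ij = (h_i + h_j) + delta_ij.  The planted signs therefore survive
    relative zero-calling at tolerances up to ~15%, and classification at
    tol=0 recovers them exactly.  All values sit on a dyadic lattice
    (quarters), so they round-trip through decimal TSV without floating-point
    residue that would corrupt exact zero deltas.  Row ids encode the planted
    (canonical) motif, recoverable via :func:`planted_motif`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    motifs = enumerate_motifs()
    rows = []
    for i in range(n):
        motif = motifs[i % len(motifs)]
        h1 = int(rng.integers(20, 41)) / 4.0  # 5.0 .. 10.0 in quarter steps
        h2 = int(rng.integers(20, 41)) / 4.0
        deltas = []
        for sign, mono_sum in zip(motif.signs(), (2 * h1, h1 + h2, 2 * h2)):
            lo = max(int(0.8 * mono_sum), 1)  # quarter units: ~0.2 .. 0.4 of the sum
            hi = max(int(1.6 * mono_sum), lo + 1)
            deltas.append(sign * int(rng.integers(lo, hi + 1)) / 4.0)
        x11 = 2 * h1 + deltas[0]
        x12 = h1 + h2 + deltas[1]
        x22 = 2 * h2 + deltas[2]
        q = PhenotypeQuintet(x11, x12, x22, h1, h2)
        planted = call_signs(q, tol=0.0).canonical()  # orientation-safe annotation
        rows.append(
            {
                "id": f"q{i:03d}:{planted.token}",
                "x11": x11, "x12": x12, "x22": x22, "h1": h1, "h2": h2,
            }
        )
    return pd.DataFrame(rows, columns=QUINTET_COLUMNS)
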