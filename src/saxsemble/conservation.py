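"""Sequence conservation versus conformational conservation.

The sequence conservation score (SCS) of each reference residue is an
information-based column score from a multiple alignment: 1 − H/2 bits over
{A, C, G, U} (gaps excluded from the entropy but penalized through the
column's non-gap occupancy), min-max rescaled to [0, 1] across residues.
The 3D conformation conservation score (3DCS) is one minus the min-max
normalized per-residue r.m.s.f. across the conformer ensemble.  The two are
correlated residue-by-residue; residues that are strongly conserved in
sequence yet conformationally mobile (or vice versa) are flagged as
anticorrelated and the correlation is recomputed without them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy.stats import pearsonr

__all__ = [
    "MultipleAlignment",
    "ConservationTable",
    "read_alignment",
    "write_alignment",
    "map_columns_to_reference",
    "sequence_conservation_score",
    "conformation_conservation_score",
    "build_conservation_table",
    "correlate_and_flag",
]

_BASES = ("A", "C", "G", "U")
_IUPAC = set("ACGUNRYSWKMBDHV-.")


@dataclass(frozen=True)
class MultipleAlignment:
    """Aligned RNA sequences: equal-length upper-case rows over {A,C,G,U,-,...}."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        length = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise ValueError(f"ragged alignment: {sid!r} has length {len(row)} != {length}")
            bad = set(row) - _IUPAC
            if bad:
                raise ValueError(f"{sid!r}: characters outside IUPAC RNA codes: {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None


@dataclass(frozen=True)
class ConservationTable:
    """Per-residue SCS, r.m.s.f., 3DCS and anticorrelation flags."""

    table: pd.DataFrame  # index: residue number; columns: scs, rmsf, threeDCS, flag

    def __post_init__(self) -> None:
        required = {"scs", "rmsf", "threeDCS", "flag"}
        if not required <= set(self.table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        for col in ("scs", "threeDCS"):
            v = self.table[col].to_numpy()
            if np.any((v < -1e-9) | (v > 1 + 1e-9)):
                raise ValueError(f"{col} out of [0, 1]")


def _normalize_row(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_alignment(path: str | Path, fmt: str | None = None) -> MultipleAlignment:
    """Read a Stockholm or aligned-FASTA multiple alignment.

    Rows are case-folded to upper and DNA T is mapped to U.  The format is
    inferred from the extension when ``fmt`` is None (``.sto``/``.stk`` →
    stockholm, else fasta).
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in {".sto", ".stk", ".stockholm"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return MultipleAlignment(
        ids=tuple(rec.id for rec in aln),
        rows=tuple(_normalize_row(str(rec.seq)) for rec in aln),
    )


def write_alignment(msa: MultipleAlignment, path: str | Path, fmt: str = "stockholm") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "stockholm":
            fh.write("# STOCKHOLM 1.0\n")
            width = max(len(i) for i in msa.ids) + 2
            for sid, row in zip(msa.ids, msa.rows):
                fh.write(f"{sid:<{width}}{row}\n")
            fh.write("//\n")
        elif fmt == "fasta":
            for sid, row in zip(msa.ids, msa.rows):
                fh.write(f">{sid}\n{row}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


def map_columns_to_reference(msa: MultipleAlignment, reference_id: str) -> dict[int, int]:
    """Map alignment columns (0-based) to reference residue numbers (1-based).

    Non-gap columns of the reference row map to consecutive residue numbers;
    gap columns are unmapped.
    """
    ref = msa.row(reference_id)
    mapping: dict[int, int] = {}
    residue = 0
    for j, ch in enumerate(ref):
        if ch not in "-.":
            residue += 1
            mapping[j] = residue
    if not mapping:
        raise ValueError(f"reference {reference_id!r} is all gaps")
    return mapping


def _column_score(column: str) -> float:
    """Occupancy-weighted information score of one column, in [0, 1].

    1 − H/log2(4) over {A,C,G,U} frequencies among non-gap, unambiguous
    characters, multiplied by the non-gap fraction of the column.
    """
    counts = np.array([column.count(b) for b in _BASES], dtype=float)
    non_gap = sum(1 for c in column if c not in "-.")
    if counts.sum() == 0:
        return 0.0
    p = counts / counts.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    occupancy = non_gap / len(column)
    return (1.0 - h / 2.0) * occupancy


def sequence_conservation_score(
    msa: MultipleAlignment,
    mapping: Mapping[int, int],
    rescale: bool = True,
) -> pd.Series:
    """Per-residue sequence conservation score.

    Scores the mapped alignment columns with the entropy/occupancy score and
    (by default) min-max rescales across residues to [0, 1].  Returns a
    Series indexed by residue number.
    """
    residues, scores = [], []
    for col, residue in sorted(mapping.items(), key=lambda kv: kv[1]):
        residues.append(residue)
        scores.append(_column_score(msa.column(col)))
    s = np.array(scores)
    if rescale:
        span = np.ptp(s)
        s = (s - s.min()) / span if span > 0 else np.ones_like(s)
    return pd.Series(s, index=pd.Index(residues, name="residue"), name="scs")


def conformation_conservation_score(rmsf: np.ndarray) -> np.ndarray:
    """3DCS: one minus the min-max normalized per-residue r.m.s.f.

    The residue with the smallest fluctuation scores 1 (most conformationally
    conserved); the largest scores 0.  A constant r.m.s.f. vector is
    degenerate — all scores are defined as 1.
    """
    rmsf = np.asarray(rmsf, dtype=float)
    if rmsf.size == 0:
        raise ValueError("empty rmsf vector")
    span = np.ptp(rmsf)
    if span == 0:
        return np.ones_like(rmsf)
    return 1.0 - (rmsf - rmsf.min()) / span


def build_conservation_table(
    scs: pd.Series,
    rmsf: pd.Series,
    core_residues: Sequence[int] = (),
    flag_quantile: float = 0.25,
) -> ConservationTable:
    """Join SCS and r.m.s.f. on residue number and flag anticorrelated residues.

    Residues in the upper ``1 − flag_quantile`` tail of one score and the
    lower ``flag_quantile`` tail of the other are flagged
    ``high-SCS/low-3DCS`` or ``low-SCS/high-3DCS``; invariant-core residues
    are labelled ``core``; everything else ``correlated``.
    """
    common = scs.index.intersection(rmsf.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 residues shared between SCS and rmsf")
    scs_v = scs.loc[common].to_numpy()
    rmsf_v = rmsf.loc[common].to_numpy(dtype=float)
    tdcs = conformation_conservation_score(rmsf_v)

    lo_q, hi_q = flag_quantile, 1.0 - flag_quantile
    scs_lo, scs_hi = np.quantile(scs_v, [lo_q, hi_q])
    t_lo, t_hi = np.quantile(tdcs, [lo_q, hi_q])
    flags = np.full(len(common), "correlated", dtype=object)
    flags[(scs_v >= scs_hi) & (tdcs <= t_lo)] = "high-SCS/low-3DCS"
    flags[(scs_v <= scs_lo) & (tdcs >= t_hi)] = "low-SCS/high-3DCS"
    core = set(int(r) for r in core_residues)
    flags[[int(r) in core for r in common]] = "core"

    frame = pd.DataFrame(
        {"scs": scs_v, "rmsf": rmsf_v, "threeDCS": tdcs, "flag": flags},
        index=pd.Index(common, name="residue"),
    )
    return ConservationTable(table=frame)


def correlate_and_flag(
    table: ConservationTable,
    exclusion: Sequence[int] | None = None,
    squared: bool = False,
) -> dict:
    """Pearson correlation of SCS against 3DCS, with and without flagged residues.

    ``exclusion`` defaults to the residues flagged anticorrelated in the
    table (both high-SCS/low-3DCS and low-SCS/high-3DCS).  ``squared``
    additionally reports the correlation on squared scores.  Returns a dict
    with ``r_overall``, ``r_excluding_flagged``, and the flagged residue
    sets.
    """
    t = table.table
    scs, tdcs = t["scs"].to_numpy(), t["threeDCS"].to_numpy()
    if len(t) < 3:
        raise ValueError("need at least 3 residues")
    if np.ptp(scs) == 0 or np.ptp(tdcs) == 0:
        raise ValueError("degenerate variance: a score column is constant")
    r_all = float(pearsonr(scs, tdcs)[0])

    hi_lo = t.index[t["flag"] == "high-SCS/low-3DCS"]
    lo_hi = t.index[t["flag"] == "low-SCS/high-3DCS"]
    if exclusion is None:
        excluded = set(hi_lo) | set(lo_hi)
    else:
        excluded = set(int(r) for r in exclusion)
    keep = ~t.index.isin(excluded)
    if keep.sum() >= 3 and np.ptp(scs[keep]) > 0 and np.ptp(tdcs[keep]) > 0:
        r_excl = float(pearsonr(scs[keep], tdcs[keep])[0])
    else:
        r_excl = float("nan")

    out = {
        "r_overall": r_all,
        "r_excluding_flagged": r_excl,
        "flagged_high_scs_low_3dcs": sorted(int(r) for r in hi_lo),
        "flagged_low_scs_high_3dcs": sorted(int(r) for r in lo_hi),
        "n_excluded": int(len(excluded)),
    }
    if squared:
        out["r_squared_scores"] = float(pearsonr(scs**2, tdcs**2)[0])
    return out
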