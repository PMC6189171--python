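"""Degenerate two-half-site motif screening of proteomes.

Immunoreceptor tyrosine-based activation motifs (ITAMs) consist of two
YxxL/I half-sites separated by a short spacer.  Signaling can be carried by
atypical, receptor-independent proteins bearing the same arrangement, so the
screen here scans whole proteomes with a loosely defined probe

    Tyr-X-X-(Leu/Ile)-X(6..12)-Tyr-X-X-(Leu/Ile)

ranks every motif-bearing protein by its expression across RNA-seq abundance
tables, and applies rule-based exclusion filters (secreted, nuclear-only,
sterically hindered ITAM, known ITAM receptor, ...) to reduce the ranked
candidates to a shortlist of plausible membrane-proximal transducers.

Coordinates are 1-based and inclusive throughout, matching the residue
numbering conventions used for, e.g., the moesin Y191/Y205 tyrosine pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: symbols that may appear in sequences but never satisfy anchor/tail positions
UNKNOWN_SYMBOLS = set("XBZJUO*")


class PatternError(ValueError):
    """Raised for malformed motif pattern configuration."""


@dataclass(frozen=True)
class MotifPattern:
    """A two-half-site probe: anchor-x-x-tail ... spacer ... anchor-x-x-tail."""

    anchor1: str = "Y"
    tail1: frozenset = frozenset("LI")
    spacer_min: int = 6
    spacer_max: int = 12
    anchor2: str = "Y"
    tail2: frozenset = frozenset("LI")

    def __post_init__(self):
        alphabet = set(AMINO_ACIDS)
        for name in ("anchor1", "anchor2"):
            a = getattr(self, name)
            if len(a) != 1 or a not in alphabet:
                raise PatternError(f"{name} must be a single standard residue, got {a!r}")
        for name in ("tail1", "tail2"):
            t = frozenset(getattr(self, name))
            if not t or not t <= alphabet:
                raise PatternError(f"{name} must be a nonempty subset of the 20 residues")
            object.__setattr__(self, name, t)
        if not (0 < self.spacer_min <= self.spacer_max):
            raise PatternError(
                f"need 0 < spacer_min <= spacer_max, got ({self.spacer_min}, {self.spacer_max})"
            )

    @property
    def min_length(self) -> int:
        return 8 + self.spacer_min

    @property
    def max_length(self) -> int:
        return 8 + self.spacer_max

    @classmethod
    def from_string(cls, text: str) -> "MotifPattern":
        """Parse a PROSITE-flavoured probe such as ``Y-X-X-[LI]-X(6,12)-Y-X-X-[LI]``."""
        m = re.fullmatch(
            r"([A-Z])-X-X-\[([A-Z]+)\]-X\((\d+),(\d+)\)-([A-Z])-X-X-\[([A-Z]+)\]",
            text.strip().upper().replace(" ", ""),
        )
        if m is None:
            raise PatternError(f"cannot parse motif pattern {text!r}")
        return cls(
            anchor1=m.group(1),
            tail1=frozenset(m.group(2)),
            spacer_min=int(m.group(3)),
            spacer_max=int(m.group(4)),
            anchor2=m.group(5),
            tail2=frozenset(m.group(6)),
        )

    def to_string(self) -> str:
        t1 = "".join(sorted(self.tail1))
        t2 = "".join(sorted(self.tail2))
        return (
            f"{self.anchor1}-X-X-[{t1}]-X({self.spacer_min},{self.spacer_max})"
            f"-{self.anchor2}-X-X-[{t2}]"
        )


@dataclass(frozen=True)
class MotifHit:
    """One probe match.  ``start``/``end`` are 1-based inclusive residue indices."""

    protein_id: str
    start: int
    spacer: int
    end: int
    matched_seq: str

    def __post_init__(self):
        if self.end != self.start + 7 + self.spacer:
            raise ValueError("inconsistent hit geometry")


def scan_sequence(
    sequence: str, pattern: MotifPattern | None = None, protein_id: str = ""
) -> list[MotifHit]:
    """Return every (start, spacer) probe match in ``sequence``.

    Overlapping and nested matches are all reported, sorted by (start, spacer).
    Unknown symbols (X, B, Z, *, ...) never satisfy anchor or tail positions
    but may occupy wildcard/spacer positions.
    """
    pattern = pattern or MotifPattern()
    seq = sequence.upper()
    n = len(seq)
    if n < pattern.min_length:
        return []
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype="S1")
    a1 = arr == pattern.anchor1.encode()
    a2 = arr == pattern.anchor2.encode()
    t1 = np.isin(arr, [c.encode() for c in pattern.tail1])
    t2 = np.isin(arr, [c.encode() for c in pattern.tail2])

    hits: list[MotifHit] = []
    for i in map(int, np.flatnonzero(a1)):  # 0-based index of first anchor
        if not (i + 3 < n and t1[i + 3]):
            continue
        for s in range(pattern.spacer_min, pattern.spacer_max + 1):
            j = i + 4 + s  # second anchor
            if j + 3 >= n:
                break
            if a2[j] and t2[j + 3]:
                hits.append(
                    MotifHit(
                        protein_id=protein_id,
                        start=i + 1,
                        spacer=s,
                        end=i + 1 + 7 + s,
                        matched_seq=seq[i : i + 8 + s],
                    )
                )
    hits.sort(key=lambda h: (h.start, h.spacer))
    return hits


def read_proteome(path: str | Path) -> dict[str, str]:
    """Read a FASTA proteome into an ordered {id: sequence} mapping."""
    records: dict[str, str] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise IOError(f"unreadable FASTA {path}: {exc}") from exc
    for idx, rec in enumerate(parsed):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record ID {rec.id!r} at record {idx}")
        records[rec.id] = str(rec.seq)
    return records


def scan_proteome(
    proteome: Mapping[str, str], pattern: MotifPattern | None = None
) -> pd.DataFrame:
    """Scan every protein; return one row per protein with >= 1 hit.

    An "independent hit" is a unique motif-bearing protein; the per-protein
    match count is kept in ``hit_count``.
    """
    pattern = pattern or MotifPattern()
    if len(set(proteome)) != len(proteome):
        raise ValueError("duplicate protein IDs in proteome")
    rows = []
    for pid, seq in proteome.items():
        hits = scan_sequence(seq, pattern, protein_id=pid)
        if hits:
            rows.append(
                {
                    "protein_id": pid,
                    "gene": pid.split("|")[-1],
                    "hit_count": len(hits),
                    "first_start": hits[0].start,
                    "first_spacer": hits[0].spacer,
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "gene", "hit_count", "first_start", "first_spacer"]
    )


def rank_candidates(
    table: pd.DataFrame,
    expression: Sequence[Mapping[str, float] | pd.Series],
    top_n: int = 25,
) -> pd.DataFrame:
    """Rank motif-bearing proteins by expression across abundance tables.

    Each dataset contributes a within-dataset percentile rank in (0, 1]
    (highest abundance -> 1); a gene absent from a dataset contributes 0.
    The aggregate score is the mean percentile rank across datasets, so the
    result is invariant to any monotone rescaling of a single table
    (counts, FPKM and TPM mix freely).  Rows are sorted by descending
    aggregate score with ties broken lexicographically by gene symbol, and
    the leading ``top_n`` rows are flagged.
    """
    if len(expression) == 0:
        raise ValueError("at least one expression table is required")
    out = table.copy()
    pct_cols = []
    for k, tab in enumerate(expression):
        ser = pd.Series(dict(tab), dtype=float)
        if (ser < 0).any():
            raise ValueError(f"negative abundance in dataset {k}")
        pct = ser.rank(pct=True)  # midranks for ties; in (0, 1]
        col = f"pct_rank_{k}"
        out[col] = out["gene"].map(pct).fillna(0.0)
        out[f"abundance_{k}"] = out["gene"].map(ser)
        pct_cols.append(col)
    out["aggregate_score"] = out[pct_cols].mean(axis=1)
    out = out.sort_values(
        ["aggregate_score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["is_top"] = np.arange(len(out)) < top_n
    return out


@dataclass
class ExclusionRules:
    """Ordered exclusion predicates (highest precedence first)."""

    order: list[str] = field(
        default_factory=lambda: [
            "known_itam_receptor",
            "secreted",
            "nuclear_only",
            "no_membrane_binding",
            "itam_sterically_hindered",
            "poor_knockdown",
        ]
    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExclusionRules":
        tab = pd.read_csv(path, sep="\t")
        tab = tab.sort_values("precedence")
        return cls(order=list(tab["rule"]))


def apply_exclusions(
    table: pd.DataFrame,
    annotations: pd.DataFrame,
    rules: ExclusionRules | None = None,
) -> pd.DataFrame:
    """Flag each candidate with its first (highest-precedence) failing rule.

    ``annotations`` is a gene-indexed boolean table whose columns are rule
    names; True means the rule disqualifies the gene.  The shortlist is the
    passing rows in rank order (``excluded`` False).
    """
    rules = rules or ExclusionRules()
    unknown = set(annotations.columns) - set(rules.order)
    if unknown:
        raise ValueError(f"annotation references unknown rule name(s): {sorted(unknown)}")
    out = table.copy()
    reasons = []
    for gene in out["gene"]:
        reason = ""
        if gene in annotations.index:
            row = annotations.loc[gene]
            for rule in rules.order:
                if rule in annotations.columns and bool(row[rule]):
                    reason = rule
                    break
        reasons.append(reason)
    out["exclusion_reason"] = reasons
    out["excluded"] = out["exclusion_reason"] != ""
    return out


def shortlist(table: pd.DataFrame) -> pd.DataFrame:
    """Passing rows of an exclusion-annotated candidate table, in rank order."""
    return table.loc[~table["excluded"]].reset_index(drop=True)


def brute_force_scan(
    sequence: str, pattern: MotifPattern | None = None, protein_id: str = ""
) -> list[MotifHit]:
    """Independent exhaustive reference scanner: tests every (i, s) pair.

    Deliberately naive (per-position character tests, no vectorisation);
    used to cross-check :func:`scan_sequence`.
    """
    pattern = pattern or MotifPattern()
    seq = sequence.upper()
    hits = []
    for i in range(len(seq)):
        for s in range(pattern.spacer_min, pattern.spacer_max + 1):
            last = i + 7 + s
            if last >= len(seq):
                continue
            ok = (
                seq[i] == pattern.anchor1
                and seq[i + 3] in pattern.tail1
                and seq[i + 4 + s] == pattern.anchor2
                and seq[i + 7 + s] in pattern.tail2
            )
            if ok:
                hits.append(
                    MotifHit(protein_id, i + 1, s, i + 8 + s, seq[i : i + 8 + s])
                )
    hits.sort(key=lambda h: (h.start, h.spacer))
    return hits


def expected_match_probability(pattern: MotifPattern | None = None) -> float:
    """Expected number of matches per start position under uniform residues.

    A fixed start can match with each allowed spacer length independently of
    the others, so the expected hit count per start is the per-spacer match
    probability times the number of spacer choices.
    """
    pattern = pattern or MotifPattern()
    per_spacer = (1 / 20) * (len(pattern.tail1) / 20) * (1 / 20) * (len(pattern.tail2) / 20)
    return per_spacer * (pattern.spacer_max - pattern.spacer_min + 1)
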