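"""Differential-expression filtering and coding-potential screening.

The screen keeps features whose high-fat vs low-fat contrast exceeds a
log2 fold-change threshold (|log2FC| > 2 by default — absolute, because the
validated genes include a downregulated one), then removes lncRNA candidates
with strong protein-coding potential.  Coding potential comes from an
ingested score table when available; otherwise a built-in open-reading-frame
heuristic over the transcript sequence is applied, flagging a transcript as
coding-like when its longest ORF is >= 300 nt or covers >= 30% of the
transcript.  Candidates with no evidence either way are retained but
flagged: the screen removes strong coding potential, and absence of
evidence is not evidence of coding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple

import pandas as pd

logger = logging.getLogger(__name__)

CodingLabel = Literal["coding", "noncoding", "weak_coding"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
VALID_NT = frozenset("ACGTN")


@dataclass(frozen=True)
class DERecord:
    """One feature's differential-expression summary (HF vs LF contrast)."""

    feature_id: str
    feature_class: Literal["mRNA", "lncRNA"]
    log2fc: float
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(
                f"record {self.feature_id!r}: pvalue {self.pvalue} not in [0, 1]"
            )


@dataclass(frozen=True)
class CodingPotentialRecord:
    """An externally computed coding-potential call for one transcript."""

    feature_id: str
    score: float
    label: CodingLabel


class ScreenResult(NamedTuple):
    """Noncoding screen output: retained records and no-evidence flags."""

    retained: list[DERecord]
    missing_evidence: list[str]


def filter_differential(
    records: Iterable[DERecord],
    logfc_threshold: float = 2.0,
    p_threshold: float | None = None,
    absolute: bool = True,
) -> list[DERecord]:
    """Retain records exceeding the fold-change (and optional p) threshold.

    With ``absolute`` (default) the rule is ``|log2fc| > logfc_threshold``;
    otherwise one-sided ``log2fc > logfc_threshold``.  A strict inequality in
    both modes.  Output is ordered by |log2fc| descending, ties broken by
    feature_id ascending, so reruns are deterministic.
    """
    if logfc_threshold <= 0:
        raise ValueError(f"logfc_threshold must be positive, got {logfc_threshold}")
    kept = []
    for rec in records:
        if not math.isfinite(rec.log2fc):
            raise ValueError(
                f"record {rec.feature_id!r}: non-finite log2fc {rec.log2fc}"
            )
        stat = abs(rec.log2fc) if absolute else rec.log2fc
        if stat <= logfc_threshold:
            continue
        if p_threshold is not None:
            if rec.pvalue is None or rec.pvalue >= p_threshold:
                continue
        kept.append(rec)
    kept.sort(key=lambda r: (-abs(r.log2fc), r.feature_id))
    return kept


def longest_orf(seq: str) -> int:
    """Length in nt of the longest ATG..stop ORF over the 3 forward frames.

    The length includes the stop codon; 0 when no complete ORF exists.
    Codons containing N never match the start or a stop.
    """
    seq = seq.upper()
    invalid = set(seq) - VALID_NT
    if invalid:
        raise ValueError(f"invalid nucleotide characters: {sorted(invalid)}")
    best = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, i + 3 - start)
                start = None
    return best


def is_coding_by_orf(
    seq: str,
    min_orf_nt: int = 300,
    min_orf_fraction: float = 0.3,
) -> bool:
    """ORF heuristic: coding-like if the longest ORF is long in absolute
    terms or relative to the transcript."""
    orf = longest_orf(seq)
    if not seq:
        return False
    return orf >= min_orf_nt or orf / len(seq) >= min_orf_fraction


def screen_noncoding(
    candidates: Iterable[DERecord],
    cp: Iterable[CodingPotentialRecord] | None = None,
    fallback_sequences: Mapping[str, str] | None = None,
    min_orf_nt: int = 300,
    min_orf_fraction: float = 0.3,
) -> ScreenResult:
    """Remove lncRNA candidates with strong coding potential.

    Precedence per candidate: an explicit coding-potential label wins
    (``coding`` removed, ``noncoding``/``weak_coding`` kept); otherwise the
    ORF heuristic on the provided sequence; otherwise the candidate is
    retained and listed in ``missing_evidence``.
    """
    labels = {r.feature_id: r.label for r in cp} if cp is not None else {}
    seqs = fallback_sequences or {}
    retained: list[DERecord] = []
    missing: list[str] = []
    for rec in candidates:
        if rec.feature_class != "lncRNA":
            raise ValueError(
                f"screen_noncoding expects lncRNA candidates, got "
                f"{rec.feature_id!r} with class {rec.feature_class!r}"
            )
        label = labels.get(rec.feature_id)
        if label is not None:
            if label != "coding":
                retained.append(rec)
            continue
        seq = seqs.get(rec.feature_id)
        if seq is not None:
            if not is_coding_by_orf(seq, min_orf_nt, min_orf_fraction):
                retained.append(rec)
            continue
        missing.append(rec.feature_id)
        retained.append(rec)
    if missing:
        logger.warning(
            "screen_noncoding: %d candidates retained without coding-potential "
            "evidence", len(missing)
        )
    return ScreenResult(retained=retained, missing_evidence=missing)


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a DE table (TSV/CSV with feature_id, class, log2fc, pvalue)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"feature_id", "class", "log2fc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        pval = row.get("pvalue")
        if pval is not None and math.isnan(float(pval)):
            pval = None
        records.append(
            DERecord(
                feature_id=str(row["feature_id"]),
                feature_class=str(row["class"]),
                log2fc=float(row["log2fc"]),
                pvalue=None if pval is None else float(pval),
            )
        )
    return records


def read_cp_table(path: str | Path) -> list[CodingPotentialRecord]:
    """Read a coding-potential score table (TSV: feature_id, score, label)."""
    df = pd.read_csv(path, sep="\t")
    return [
        CodingPotentialRecord(
            feature_id=str(r.feature_id), score=float(r.score), label=str(r.label)
        )
        for r in df.itertuples(index=False)
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
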