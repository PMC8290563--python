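"""Proximity pairing of candidate mRNAs and lncRNAs.

The central screening step: an mRNA and a lncRNA on the same chromosome
whose gene spans lie within a genomic window (50 kb by default) of each
other form an HML (hepatic mRNA-lncRNA) pair — the operational definition
of a candidate cis-regulatory relationship.  The window comparison is
boundary-inclusive (distance <= window pairs) and many-to-many: one lncRNA
may pair with several mRNAs and vice versa.

Pairing uses the per-chromosome interval index, querying each lncRNA span
expanded by the window; the result provably equals the quadratic all-pairs
enumeration and is tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .annotations import FeatureCatalog, GenomicFeature, feature_distance

Relation = Literal["overlapping", "upstream_of_mrna", "downstream_of_mrna"]


@dataclass(frozen=True)
class HMLPair:
    """An mRNA-lncRNA pair within the proximity window."""

    mrna_id: str
    lncrna_id: str
    chrom: str
    distance_bp: int
    relation: Relation


def _relation(mrna: GenomicFeature, lnc: GenomicFeature) -> Relation:
    """Relative placement of the lncRNA on the reference strand.

    'overlapping' requires a genuine interval intersection; an abutting
    lncRNA (distance 0 but no shared base) is classified by position.
    """
    if mrna.start < lnc.end and lnc.start < mrna.end:
        return "overlapping"
    if lnc.end <= mrna.start:
        return "upstream_of_mrna"
    return "downstream_of_mrna"


def pair_by_proximity(
    mrnas: FeatureCatalog,
    lncrnas: FeatureCatalog,
    window_bp: int = 50_000,
    inclusive: bool = True,
) -> list[HMLPair]:
    """All same-chromosome mRNA-lncRNA pairs within ``window_bp``.

    ``inclusive`` (default) keeps pairs with distance == window_bp exactly.
    Output order is deterministic: chrom, then mrna_id, then lncrna_id.
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be >= 0, got {window_bp}")
    if len(mrnas) == 0 or len(lncrnas) == 0:
        raise ValueError("both feature sets must be non-empty")
    pairs = []
    for lnc in lncrnas:
        # expanding the lncRNA span by window+1 on each side makes the
        # half-open index query capture every gap <= window exactly
        lo = max(lnc.start - window_bp - 1, 0)
        hi = lnc.end + window_bp + 1
        for mrna in mrnas.query(lnc.chrom, lo, hi):
            dist = feature_distance(mrna, lnc)
            assert dist is not None
            if dist > window_bp or (not inclusive and dist == window_bp):
                continue
            pairs.append(
                HMLPair(
                    mrna_id=mrna.feature_id,
                    lncrna_id=lnc.feature_id,
                    chrom=mrna.chrom,
                    distance_bp=dist,
                    relation=_relation(mrna, lnc),
                )
            )
    pairs.sort(key=lambda p: (p.chrom, p.mrna_id, p.lncrna_id))
    return pairs


def summarize_pairs(pairs: Iterable[HMLPair]) -> dict:
    """Per-chromosome counts, distance quantiles and overlap fraction."""
    pairs = list(pairs)
    per_chrom: dict[str, int] = {}
    for p in pairs:
        per_chrom[p.chrom] = per_chrom.get(p.chrom, 0) + 1
    if not pairs:
        return {
            "n_pairs": 0,
            "per_chrom": {},
            "distance_quantiles": {q: 0.0 for q in (0, 25, 50, 75, 100)},
            "overlap_fraction": 0.0,
        }
    dists = np.array([p.distance_bp for p in pairs], dtype=float)
    quantiles = {
        q: float(np.percentile(dists, q)) for q in (0, 25, 50, 75, 100)
    }
    overlap = sum(1 for p in pairs if p.relation == "overlapping") / len(pairs)
    return {
        "n_pairs": len(pairs),
        "per_chrom": dict(sorted(per_chrom.items())),
        "distance_quantiles": quantiles,
        "overlap_fraction": overlap,
    }


def write_pairs_tsv(pairs: Iterable[HMLPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mrna_id\tlncrna_id\tchrom\tdistance_bp\trelation\n")
        for p in pairs:
            fh.write(
                f"{p.mrna_id}\t{p.lncrna_id}\t{p.chrom}\t"
                f"{p.distance_bp}\t{p.relation}\n"
            )


def write_pairs_bedpe(
    pairs: Iterable[HMLPair],
    mrnas: FeatureCatalog,
    lncrnas: FeatureCatalog,
    path: str | Path,
) -> None:
    """BEDPE export (mRNA interval, lncRNA interval) for genome browsers."""
    with open(path, "w") as fh:
        for p in pairs:
            m, l = mrnas[p.mrna_id], lncrnas[p.lncrna_id]
            fh.write(
                "\t".join(
                    [
                        m.chrom, str(m.start), str(m.end),
                        l.chrom, str(l.start), str(l.end),
                        f"{p.mrna_id}--{p.lncrna_id}",
                        str(p.distance_bp),
                        m.strand if m.strand in "+-" else ".",
                        l.strand if l.strand in "+-" else ".",
                    ]
                )
                + "\n"
            )
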