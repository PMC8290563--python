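"""Genomic feature catalogs with explicit coordinate conventions.

Internally every feature is stored 0-based half-open (``[start, end)``),
the BED convention.  GTF input (1-based inclusive) is shifted on read and
shifted back on write; BED input is ingested as-is.  Chromosome names are
normalized by stripping a leading ``chr`` prefix so Ensembl- and UCSC-style
inputs can be mixed.

Distances between features are boundary gaps between collapsed gene spans:
0 for overlapping or abutting loci, otherwise the number of bases strictly
between them.  Features on different chromosomes have no defined distance
(``None``).  Strand is stored but ignored by the default distance; a
TSS-to-TSS mode is available for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

FeatureClass = Literal["mRNA", "lncRNA"]
Strand = Literal["+", "-", "."]

#: default mapping from GTF biotype attribute values to feature classes
DEFAULT_CLASS_MAP: dict[str, FeatureClass] = {
    "protein_coding": "mRNA",
    "mRNA": "mRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "antisense_RNA": "lncRNA",
    "processed_transcript": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
}


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix so 'chr1' and '1' compare equal."""
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class GenomicFeature:
    """A located mRNA or lncRNA locus (collapsed gene span).

    Coordinates are 0-based half-open; ``start < end`` always holds.
    """

    feature_id: str
    feature_class: FeatureClass
    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.feature_class not in ("mRNA", "lncRNA"):
            raise ValueError(
                f"feature {self.feature_id!r}: unknown class {self.feature_class!r}"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end on the annotated strand."""
        return self.end - 1 if self.strand == "-" else self.start


class FeatureCatalog:
    """A collection of features indexed by id and by genomic interval."""

    def __init__(self, features: Iterable[GenomicFeature] = ()) -> None:
        self._by_id: dict[str, GenomicFeature] = {}
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            self.add(f)

    def add(self, feature: GenomicFeature) -> None:
        if feature.feature_id in self._by_id:
            raise ValueError(f"duplicate feature_id {feature.feature_id!r}")
        self._by_id[feature.feature_id] = feature
        self._trees.setdefault(feature.chrom, IntervalTree()).addi(
            feature.start, feature.end, feature
        )

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[GenomicFeature]:
        return iter(self._by_id.values())

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def __getitem__(self, feature_id: str) -> GenomicFeature:
        return self._by_id[feature_id]

    def get(self, feature_id: str) -> GenomicFeature | None:
        return self._by_id.get(feature_id)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def query(self, chrom: str, start: int, end: int) -> list[GenomicFeature]:
        """Features whose intervals intersect ``[start, end)`` on ``chrom``."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda f: (f.start, f.end, f.feature_id))
        return hits

    def subset(self, feature_ids: Iterable[str]) -> "FeatureCatalog":
        """A new catalog restricted to ``feature_ids``; unknown ids are skipped."""
        return FeatureCatalog(
            self._by_id[i] for i in feature_ids if i in self._by_id
        )

    def by_class(self, feature_class: FeatureClass) -> "FeatureCatalog":
        return FeatureCatalog(
            f for f in self if f.feature_class == feature_class
        )


def feature_distance(
    a: GenomicFeature,
    b: GenomicFeature,
    mode: Literal["span", "tss"] = "span",
) -> int | None:
    """Genomic distance between two features, or ``None`` across chromosomes.

    ``span`` (default): boundary gap between the collapsed spans — 0 when the
    intervals overlap or abut, otherwise ``max(starts) - min(ends)``.
    ``tss``: absolute distance between transcription start sites
    (experimental; sensitive to strand annotation quality).

    Symmetric in its arguments; strand is ignored in ``span`` mode.
    """
    if a.chrom != b.chrom:
        return None
    if mode == "tss":
        return abs(a.tss - b.tss)
    gap = max(a.start, b.start) - min(a.end, b.end)
    return max(gap, 0)


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(
    path: str | Path,
    class_map: Mapping[str, FeatureClass] | None = None,
    id_attribute: str = "gene_id",
    class_attributes: tuple[str, ...] = (
        "gene_biotype",
        "gene_type",
        "transcript_biotype",
        "transcript_type",
    ),
) -> FeatureCatalog:
    """Read a GTF file into a catalog of collapsed gene spans.

    GTF coordinates are 1-based inclusive; on read they become 0-based
    half-open via ``(start - 1, end)``.  All records sharing an
    ``id_attribute`` value are collapsed to their min-start/max-end span
    (multi-exon transcripts become one feature).  Records whose biotype does
    not map to a feature class are skipped and counted.
    """
    class_map = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    path = Path(path)
    spans: dict[str, dict] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GTF line "
                    f"({len(fields)} fields, expected 9)"
                )
            chrom, _source, _ftype, start_s, end_s, _score, strand, _frame, attr = (
                fields[:9]
            )
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise ValueError(
                    f"{path}:{lineno}: invalid 1-based interval {start1}-{end1}"
                )
            attrs = _parse_gtf_attributes(attr)
            fid = attrs.get(id_attribute)
            if fid is None:
                n_skipped += 1
                continue
            fclass = None
            for key in class_attributes:
                biotype = attrs.get(key)
                if biotype is not None and biotype in class_map:
                    fclass = class_map[biotype]
                    break
            if fclass is None:
                n_skipped += 1
                continue
            start0, end0 = start1 - 1, end1
            rec = spans.get(fid)
            if rec is None:
                spans[fid] = {
                    "chrom": normalize_chrom(chrom),
                    "start": start0,
                    "end": end0,
                    "strand": strand if strand in ("+", "-") else ".",
                    "class": fclass,
                }
            else:
                rec["start"] = min(rec["start"], start0)
                rec["end"] = max(rec["end"], end0)
    if n_skipped:
        logger.info("read_gtf(%s): skipped %d unmappable records", path, n_skipped)
    if not spans:
        raise ValueError(f"{path}: no usable features found")
    return FeatureCatalog(
        GenomicFeature(
            feature_id=fid,
            feature_class=rec["class"],
            chrom=rec["chrom"],
            start=rec["start"],
            end=rec["end"],
            strand=rec["strand"],
        )
        for fid, rec in spans.items()
    )


def write_gtf(catalog: FeatureCatalog, path: str | Path, source: str = "hmlnet") -> None:
    """Write a catalog as GTF gene records (back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for f in sorted(catalog, key=lambda f: (f.chrom, f.start, f.feature_id)):
            biotype = "protein_coding" if f.feature_class == "mRNA" else "lncRNA"
            attrs = f'gene_id "{f.feature_id}"; gene_biotype "{biotype}";'
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        source,
                        "gene",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand if f.strand in ("+", "-") else ".",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path, feature_class: FeatureClass) -> FeatureCatalog:
    """Read a BED3+ file (0-based half-open, no coordinate shift).

    Column 4 is used as the feature id when present; otherwise ids are
    auto-generated as ``<class>_<line>``.  A trailing ``|mRNA`` / ``|lncRNA``
    suffix written by :func:`write_bed` is stripped from the name.
    """
    path = Path(path)
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if len(fields) >= 4 and fields[3] != ".":
                name = fields[3]
                for suffix in ("|mRNA", "|lncRNA"):
                    if name.endswith(suffix):
                        name = name[: -len(suffix)]
            else:
                name = f"{feature_class}_{lineno}"
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            features.append(
                GenomicFeature(
                    feature_id=name,
                    feature_class=feature_class,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    if not features:
        raise ValueError(f"{path}: no usable features found")
    return FeatureCatalog(features)


def write_bed(catalog: FeatureCatalog, path: str | Path) -> None:
    """Write a catalog as BED6; the name field carries ``id|class``."""
    with open(path, "w") as fh:
        for f in sorted(catalog, key=lambda f: (f.chrom, f.start, f.feature_id)):
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        str(f.start),
                        str(f.end),
                        f"{f.feature_id}|{f.feature_class}",
                        "0",
                        f.strand if f.strand in ("+", "-") else ".",
                    ]
                )
                + "\n"
            )
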