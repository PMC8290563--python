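"""Synthetic study generator with planted ground truth.

Emulates every input the screening pipeline consumes — a toy genome with
cis mRNA-lncRNA pairs planted at controlled gaps, a differential-expression
table with a fixed number of features passing the fold-change screen,
coding-potential calls, KEGG-style gene sets with planted enrichment, a
STRING-style scored edge list with a planted hub, grouped qPCR CT tables
with planted correlations and direction patterns, and phenotype panels —
so every stage can be tested end to end without downloads.

Defaults encode the motivating study's conditions: 5,000 mRNAs of which
400 pass |log2FC| > 2, 236 candidate lncRNAs, 10 proximity pairs within
50 kb, a 5 -> 4 -> 3 annotation funnel (insulin-resistance pathway
membership, dual carbohydrate/lipid metabolic category, database-annotated
lncRNA), four groups of n = 6 animals, and the published direction and
correlation patterns (Srebf1 and Pck1 up with their lncRNAs in the
sedentary high-fat group, Cpt1b down, all reversed by exercise and
amplified in diabetes).

Everything is deterministic given the config seed; each generator draws
from its own seeded substream so the outputs are independent of call
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotations import FeatureCatalog, GenomicFeature, write_bed, write_gtf
from .de_screen import CodingPotentialRecord
from .enrichment import GeneSet
from .expression_stats import CTTable
from .network import ScoredEdge

#: the named mRNA-lncRNA pairs validated in the motivating study
PAPER_PAIR_NAMES: tuple[tuple[str, str], ...] = (
    ("Srebf1", "Gm38501"),
    ("Pck1", "Ctcflos"),
    ("Pck1", "Gm36691"),
    ("Cpt1b", "Gm44502"),
)

#: published prediabetic-group Pearson correlations for the named pairs
PAPER_PLANTED_RHO: dict[tuple[str, str], float] = {
    ("Srebf1", "Gm38501"): 0.70,
    ("Pck1", "Ctcflos"): 0.86,
    ("Pck1", "Gm36691"): 0.76,
    ("Cpt1b", "Gm44502"): 0.76,
}

#: direction of each named gene in the sedentary high-fat group vs control
PAPER_DIRECTIONS: dict[str, str] = {
    "Srebf1": "up",
    "Pck1": "up",
    "Cpt1b": "down",
}

#: group-level phenotype parameters (mean, SD): fasting glucose mg/dL,
#: fasting insulin ng/mL, and a tolerance-test glucose profile at
#: 0/30/60/90/120 min. SDs back-computed from published SEMs at n = 6.
PHENOTYPE_PARAMS: dict[str, dict] = {
    "Ctrl": {
        "glucose": (94.1, 8.3),
        "insulin_ng": (1.2, 0.12),
        "gtt": (94.0, 180.0, 160.0, 130.0, 100.0),
    },
    "HF-Sed": {
        "glucose": (122.0, 15.9),
        "insulin_ng": (5.7, 3.4),
        "gtt": (122.0, 280.0, 260.0, 220.0, 180.0),
    },
    "HF-Exe": {
        "glucose": (96.3, 19.1),
        "insulin_ng": (1.8, 0.22),
        "gtt": (96.0, 200.0, 170.0, 140.0, 110.0),
    },
    "Diabetic": {
        "glucose": (250.0, 25.0),
        "insulin_ng": (2.5, 0.8),
        "gtt": (250.0, 450.0, 430.0, 400.0, 380.0),
    },
}

GTT_MINUTES = (0.0, 30.0, 60.0, 90.0, 120.0)

# substream ids so the generators are independent of call order
_STREAM_GENOME = 1
_STREAM_DE = 2
_STREAM_CT = 3
_STREAM_PPI = 4
_STREAM_PHENO = 5
_STREAM_FASTA = 6


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # genome
    n_chroms: int = 5
    chrom_length: int = 120_000_000
    n_mrnas: int = 5000
    n_lncrnas: int = 236
    n_true_pairs: int = 10
    true_pair_max_gap: int = 40_000
    decoy_min_gap: int = 60_000
    gene_length_range: tuple[int, int] = (1_000, 5_000)
    inter_block_jitter: int = 20_000
    # differential expression
    frac_de: float = 0.08
    logfc_mean: float = 3.0
    logfc_sd: float = 0.5
    logfc_threshold: float = 2.0
    n_coding_contaminants: int = 10
    # pathways / enrichment
    n_pathways: int = 20
    pathway_size: int = 40
    enrichment_odds: float = 8.0
    n_funnel_target: int = 5
    n_funnel_dual: int = 4
    n_funnel_annotated: int = 3
    # PPI network
    hub_extra_degrees: tuple[int, ...] = (30, 20, 12, 6, 4)
    n_background_edges: int = 300
    ppi_score_threshold: float = 0.4
    # expression study
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"Ctrl": 6, "HF-Sed": 6, "HF-Exe": 6, "Diabetic": 6}
    )
    group_effect_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "Ctrl": 0.0,
            "HF-Sed": 1.0,
            "HF-Exe": -0.3,
            "Diabetic": 1.5,
        }
    )
    base_dct_mrna: float = 8.0
    base_dct_lncrna: float = 12.0
    effect_dct: float = 2.0
    ct_sd: float = 0.8
    ref_ct_mean: float = 15.0
    ref_ct_sd: float = 0.2
    pair_names: tuple[tuple[str, str], ...] = PAPER_PAIR_NAMES
    planted_rho: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(PAPER_PLANTED_RHO)
    )
    planted_directions: Mapping[str, str] = field(
        default_factory=lambda: dict(PAPER_DIRECTIONS)
    )

    def __post_init__(self) -> None:
        if self.true_pair_max_gap >= self.decoy_min_gap:
            raise ValueError(
                "true_pair_max_gap must be < decoy_min_gap (planted pairs "
                "must be separable from decoys)"
            )
        for name, value in (
            ("n_chroms", self.n_chroms),
            ("chrom_length", self.chrom_length),
            ("n_mrnas", self.n_mrnas),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValueError("frac_de must lie in [0, 1]")
        if self.n_lncrnas < 0 or self.n_true_pairs < 0:
            raise ValueError("feature counts must be non-negative")

    @property
    def n_de_mrnas(self) -> int:
        return round(self.frac_de * self.n_mrnas)


@dataclass
class GroundTruth:
    """What was planted, for recovery checks downstream."""

    true_pairs: set[tuple[str, str]]
    de_features: set[str]
    enriched_sets: set[str]
    planted_directions: dict[str, str]
    planted_rho: dict[tuple[str, str], float]
    hub: str
    target_pathway_genes: set[str]
    dual_category_genes: set[str]
    annotated_lncrnas: set[str]
    expected_shortlist: set[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_pairs": sorted(map(list, self.true_pairs)),
            "de_features": sorted(self.de_features),
            "enriched_sets": sorted(self.enriched_sets),
            "planted_directions": dict(sorted(self.planted_directions.items())),
            "planted_rho": {
                f"{m}--{l}": r for (m, l), r in sorted(self.planted_rho.items())
            },
            "hub": self.hub,
            "target_pathway_genes": sorted(self.target_pathway_genes),
            "dual_category_genes": sorted(self.dual_category_genes),
            "annotated_lncrnas": sorted(self.annotated_lncrnas),
            "expected_shortlist": sorted(self.expected_shortlist),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_pairs={tuple(p) for p in d["true_pairs"]},
            de_features=set(d["de_features"]),
            enriched_sets=set(d["enriched_sets"]),
            planted_directions=dict(d["planted_directions"]),
            planted_rho={
                tuple(k.split("--")): v for k, v in d["planted_rho"].items()
            },
            hub=d["hub"],
            target_pathway_genes=set(d["target_pathway_genes"]),
            dual_category_genes=set(d["dual_category_genes"]),
            annotated_lncrnas=set(d["annotated_lncrnas"]),
            expected_shortlist=set(d["expected_shortlist"]),
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _planted_pairs(config: SimulationConfig) -> list[tuple[str, str]]:
    """The n_true_pairs planted pairs: named ones first, generics after."""
    pairs = list(config.pair_names)[: config.n_true_pairs]
    i = len({m for m, _ in pairs})
    while len(pairs) < config.n_true_pairs:
        pairs.append((f"HMLg{i + 1}", f"HMLl{i + 1}"))
        i += 1
    return pairs


def _feature_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Deterministic mRNA and lncRNA id lists (pair members first)."""
    pairs = _planted_pairs(config)
    pair_mrnas = list(dict.fromkeys(m for m, _ in pairs))
    pair_lncs = [l for _, l in pairs]
    if len(pair_mrnas) > config.n_mrnas:
        raise ValueError("more planted pair mRNAs than n_mrnas")
    if len(pair_lncs) > config.n_lncrnas and config.n_true_pairs > 0:
        raise ValueError("more planted pair lncRNAs than n_lncrnas")
    mrnas = pair_mrnas + [
        f"mRNA_{i:05d}" for i in range(config.n_mrnas - len(pair_mrnas))
    ]
    lncs = pair_lncs + [
        f"lnc_{i:05d}" for i in range(config.n_lncrnas - len(pair_lncs))
    ]
    return mrnas, lncs


def _funnel_sets(
    config: SimulationConfig,
) -> tuple[list[str], list[str], list[str], list[str]]:
    """(pair mRNAs, target-pathway genes, dual-category genes, annotated)."""
    pairs = _planted_pairs(config)
    pair_mrnas = list(dict.fromkeys(m for m, _ in pairs))
    target = pair_mrnas[: config.n_funnel_target]
    dual = pair_mrnas[: config.n_funnel_dual]
    annotated_mrnas = pair_mrnas[: config.n_funnel_annotated]
    annotated_lncs = [l for m, l in pairs if m in annotated_mrnas]
    return pair_mrnas, target, dual, annotated_lncs


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Ground truth implied by the config (independent of any sampling)."""
    pairs = _planted_pairs(config)
    pair_mrnas, target, dual, annotated_lncs = _funnel_sets(config)
    mrnas, lncs = _feature_names(config)
    directions = {
        m: config.planted_directions.get(m, "up") for m in pair_mrnas
    }
    rho = {
        (m, l): config.planted_rho.get((m, l), 0.7)
        for m, l in pairs
        if (m, l) in dict.fromkeys(config.pair_names)
    }
    n_short = min(config.n_funnel_target, config.n_funnel_dual, config.n_funnel_annotated)
    return GroundTruth(
        true_pairs=set(pairs),
        de_features=set(),  # filled by simulate_de_table
        enriched_sets={
            "insulin_resistance",
            "carbohydrate_metabolism",
            "lipid_metabolism",
        },
        planted_directions=directions,
        planted_rho=rho,
        hub=pair_mrnas[0] if pair_mrnas else "",
        target_pathway_genes=set(target),
        dual_category_genes=set(dual),
        annotated_lncrnas=set(annotated_lncs),
        expected_shortlist=set(pair_mrnas[:n_short]),
    )


def simulate_genome(
    config: SimulationConfig,
) -> tuple[FeatureCatalog, FeatureCatalog, GroundTruth]:
    """Place genes on a toy genome with planted cis pairs.

    Genes are laid out in blocks separated by at least ``decoy_min_gap``;
    a planted pair's lncRNA sits within ``true_pair_max_gap`` of its mRNA
    (one lncRNA downstream, a second — when an mRNA carries two — upstream).
    With ``true_pair_max_gap <= window < decoy_min_gap`` proximity pairing
    recovers exactly the planted pairs.
    """
    rng = _rng(config, _STREAM_GENOME)
    truth = make_ground_truth(config)
    pairs = _planted_pairs(config)
    mrnas, lncs = _feature_names(config)
    lncs_by_mrna: dict[str, list[str]] = {}
    for m, l in pairs:
        lncs_by_mrna.setdefault(m, []).append(l)
    for m, ls in lncs_by_mrna.items():
        if len(ls) > 2:
            raise ValueError(f"mRNA {m!r} planted with more than two lncRNAs")
    paired_lncs = {l for ls in lncs_by_mrna.values() for l in ls}

    blocks: list[tuple[str, list[str]]] = []
    for m in mrnas:
        blocks.append(("mrna", [m]) if m not in lncs_by_mrna else ("pair", [m]))
    for l in lncs:
        if l not in paired_lncs:
            blocks.append(("lnc", [l]))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    lo_len, hi_len = config.gene_length_range
    features: list[GenomicFeature] = []
    per_chrom = -(-len(blocks) // config.n_chroms)  # ceil division

    def glen() -> int:
        return int(rng.integers(lo_len, hi_len + 1))

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    for c in range(config.n_chroms):
        chrom = str(c + 1)
        cursor = int(rng.integers(0, 50_000))
        for kind, names in blocks[c * per_chrom : (c + 1) * per_chrom]:
            if kind in ("mrna", "lnc"):
                name = names[0]
                length = glen()
                fclass = "mRNA" if kind == "mrna" else "lncRNA"
                features.append(
                    GenomicFeature(name, fclass, chrom, cursor, cursor + length, strand())
                )
                cursor += length
            else:
                mrna_name = names[0]
                pair_lncs_here = lncs_by_mrna[mrna_name]
                if len(pair_lncs_here) == 2:
                    # upstream lncRNA, then the mRNA, then the downstream one
                    length = glen()
                    features.append(
                        GenomicFeature(
                            pair_lncs_here[1], "lncRNA", chrom, cursor,
                            cursor + length, strand(),
                        )
                    )
                    cursor += length + int(rng.integers(0, config.true_pair_max_gap + 1))
                length = glen()
                features.append(
                    GenomicFeature(mrna_name, "mRNA", chrom, cursor, cursor + length, strand())
                )
                cursor += length + int(rng.integers(0, config.true_pair_max_gap + 1))
                length = glen()
                features.append(
                    GenomicFeature(
                        pair_lncs_here[0], "lncRNA", chrom, cursor, cursor + length, strand()
                    )
                )
                cursor += length
            cursor += config.decoy_min_gap + int(
                rng.integers(0, config.inter_block_jitter + 1)
            )
            if cursor > config.chrom_length:
                raise ValueError(
                    f"chromosome {chrom} too short ({config.chrom_length} bp) "
                    f"to place all features with the configured gaps"
                )
    mrna_catalog = FeatureCatalog(f for f in features if f.feature_class == "mRNA")
    lnc_catalog = FeatureCatalog(f for f in features if f.feature_class == "lncRNA")
    return mrna_catalog, lnc_catalog, truth


def _rejection_normal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    keep_above: float | None = None,
    keep_below: float | None = None,
) -> np.ndarray:
    """|N(mean, sd)| magnitudes constrained to one side of a threshold."""
    out = np.abs(rng.normal(mean, sd, size=n))
    for _ in range(1000):
        bad = np.zeros(n, dtype=bool)
        if keep_above is not None:
            bad |= out <= keep_above
        if keep_below is not None:
            bad |= out >= keep_below
        if not bad.any():
            return out
        out[bad] = np.abs(rng.normal(mean, sd, size=int(bad.sum())))
    raise RuntimeError("rejection sampling failed to converge")


def simulate_de_table(
    config: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Differential-expression table with a planted set passing the screen.

    Planted DE features get |log2FC| above the threshold (magnitudes from
    |N(logfc_mean, logfc_sd)| resampled past the boundary), everything else
    stays strictly below it, so the fold-change filter recovers the planted
    set exactly.  P-values are a monotone transform of |log2FC|, hence
    rank-consistent.  Planted pair members carry their planted direction;
    when ``frac_de`` is zero nothing is differentially expressed.
    """
    rng = _rng(config, _STREAM_DE)
    mrnas, lncs = _feature_names(config)
    pairs = _planted_pairs(config)
    pair_mrnas = list(dict.fromkeys(m for m, _ in pairs))

    n_de = config.n_de_mrnas
    de_mrnas: list[str] = []
    de_lncs: list[str] = []
    if n_de > 0:
        de_mrnas = list(pair_mrnas[:n_de])
        others = [m for m in mrnas if m not in set(de_mrnas)]
        extra = n_de - len(de_mrnas)
        if extra > 0:
            de_mrnas += list(rng.choice(others, size=extra, replace=False))
        de_lncs = list(lncs)

    lnc_direction = {}
    for m, l in pairs:
        lnc_direction[l] = truth.planted_directions.get(m, "up")

    rows = []
    de_set = set(de_mrnas) | set(de_lncs)
    for fclass, ids in (("mRNA", mrnas), ("lncRNA", lncs)):
        ids_de = [i for i in ids if i in de_set]
        ids_null = [i for i in ids if i not in de_set]
        mags = _rejection_normal(
            rng, len(ids_de), config.logfc_mean, config.logfc_sd,
            keep_above=config.logfc_threshold,
        )
        for fid, mag in zip(ids_de, mags):
            direction = (
                truth.planted_directions.get(fid)
                or lnc_direction.get(fid)
                or ("up" if rng.random() < 0.5 else "down")
            )
            rows.append((fid, fclass, mag if direction == "up" else -mag))
        null_mags = _rejection_normal(
            rng, len(ids_null), 0.0, 0.5, keep_below=config.logfc_threshold
        )
        signs = np.where(rng.random(len(ids_null)) < 0.5, 1.0, -1.0)
        for fid, mag, s in zip(ids_null, null_mags, signs):
            rows.append((fid, fclass, s * mag))
    df = pd.DataFrame(rows, columns=["feature_id", "class", "log2fc"])
    from scipy.stats import norm

    df["pvalue"] = np.clip(2.0 * norm.sf(np.abs(df["log2fc"]) / 0.6), 1e-300, 1.0)
    truth.de_features = de_set
    return df.sort_values("feature_id", ignore_index=True)


def simulate_coding_potential(
    config: SimulationConfig, truth: GroundTruth
) -> list[CodingPotentialRecord]:
    """Coding-potential calls: planted pair lncRNAs are always noncoding;
    a configured number of decoy lncRNAs are coding contaminants."""
    rng = _rng(config, _STREAM_DE + 10)
    _, lncs = _feature_names(config)
    paired = {l for _, l in _planted_pairs(config)}
    decoys = [l for l in lncs if l not in paired]
    n_cont = min(config.n_coding_contaminants, len(decoys))
    contaminants = set(rng.choice(decoys, size=n_cont, replace=False)) if n_cont else set()
    records = []
    for l in lncs:
        if l in contaminants:
            records.append(CodingPotentialRecord(l, float(rng.uniform(1.0, 5.0)), "coding"))
        elif l not in paired and rng.random() < 0.1:
            records.append(
                CodingPotentialRecord(l, float(rng.uniform(-0.5, 1.0)), "weak_coding")
            )
        else:
            records.append(
                CodingPotentialRecord(l, float(rng.uniform(-5.0, -0.5)), "noncoding")
            )
    return records


def simulate_ct_table(
    config: SimulationConfig, truth: GroundTruth
) -> CTTable:
    """Grouped CT values with planted directions and pair correlations.

    The reference assay draws from N(ref_ct_mean, ref_ct_sd); each
    validation target's dCT is its class baseline shifted by
    -direction * group multiplier * effect (lower dCT = higher expression),
    plus noise.  Within every group a paired lncRNA's noise term is coupled
    to its mRNA's at the planted correlation, so the sample Pearson r on
    -dCT concentrates on the planted value.
    """
    rng = _rng(config, _STREAM_CT)
    pairs = [p for p in _planted_pairs(config) if p in truth.planted_rho]
    mrna_targets = list(dict.fromkeys(m for m, _ in pairs))
    rows = []
    for group, size in config.group_sizes.items():
        if size < 2:
            raise ValueError(f"group {group!r} needs >= 2 samples")
        mult = config.group_effect_multipliers.get(group, 0.0)
        sample_ids = [f"{group}_{i + 1:02d}" for i in range(size)]
        ref_cts = rng.normal(config.ref_ct_mean, config.ref_ct_sd, size=size)
        for sid, rc in zip(sample_ids, ref_cts):
            rows.append((sid, group, "18SrRNA", float(rc)))
        mrna_dev = {
            m: rng.normal(0.0, config.ct_sd, size=size) for m in mrna_targets
        }
        for m in mrna_targets:
            s = 1.0 if truth.planted_directions.get(m, "up") == "up" else -1.0
            mean_dct = config.base_dct_mrna - s * mult * config.effect_dct
            for sid, rc, dev in zip(sample_ids, ref_cts, mrna_dev[m]):
                rows.append((sid, group, m, float(rc + mean_dct + dev)))
        for m, l in pairs:
            rho = truth.planted_rho[(m, l)]
            s = 1.0 if truth.planted_directions.get(m, "up") == "up" else -1.0
            mean_dct = config.base_dct_lncrna - s * mult * config.effect_dct
            eps = rng.normal(0.0, config.ct_sd, size=size)
            dev = rho * mrna_dev[m] + np.sqrt(max(1.0 - rho**2, 0.0)) * eps
            for sid, rc, d in zip(sample_ids, ref_cts, dev):
                rows.append((sid, group, l, float(rc + mean_dct + d)))
    return CTTable(pd.DataFrame(rows, columns=["sample", "group", "target", "ct"]))


def simulate_ppi_and_sets(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[list[ScoredEdge], list[GeneSet], dict[str, frozenset[str]], dict[str, bool]]:
    """Scored edge list, gene sets with planted enrichment, category sidecar
    and lncRNA annotation flags.

    The three planted sets (insulin resistance + the two metabolic
    categories) over-sample differentially expressed genes at
    ``enrichment_odds``; the funnel genes appear in exactly the sets that
    realize the 5 -> 4 -> 3 shortlist; edges give the first funnel gene the
    top degree, with strictly decreasing planted degrees down the funnel.
    """
    rng = _rng(config, _STREAM_PPI)
    mrnas, lncs = _feature_names(config)
    pairs = _planted_pairs(config)
    pair_mrnas, target, dual, annotated_lncs = _funnel_sets(config)
    de = set(truth.de_features)
    background_pool = [m for m in mrnas if m not in set(pair_mrnas)]

    def weighted_fill(seeded: list[str], size: int) -> frozenset[str]:
        need = max(size - len(seeded), 0)
        weights = np.array(
            [config.enrichment_odds if m in de else 1.0 for m in background_pool]
        )
        weights /= weights.sum()
        fill = rng.choice(background_pool, size=need, replace=False, p=weights)
        return frozenset(seeded) | frozenset(map(str, fill))

    sets = [
        GeneSet(
            "insulin_resistance",
            "Insulin resistance",
            weighted_fill(target, config.pathway_size),
        ),
        GeneSet(
            "carbohydrate_metabolism",
            "Carbohydrate metabolic pathways",
            weighted_fill(dual, config.pathway_size),
        ),
        GeneSet(
            "lipid_metabolism",
            "Lipid metabolic pathways",
            weighted_fill(dual, config.pathway_size),
        ),
    ]
    for i in range(max(config.n_pathways - len(sets), 0)):
        members = rng.choice(
            background_pool, size=min(config.pathway_size, len(background_pool)),
            replace=False,
        )
        sets.append(
            GeneSet(f"pathway_{i + 1:02d}", f"Background pathway {i + 1}",
                    frozenset(map(str, members)))
        )
    categories = {
        "insulin_resistance": frozenset({"other"}),
        "carbohydrate_metabolism": frozenset({"carbohydrate_metabolism"}),
        "lipid_metabolism": frozenset({"lipid_metabolism"}),
    }
    for gs in sets[3:]:
        categories[gs.set_id] = frozenset({"other"})

    edges: list[ScoredEdge] = []
    seen: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str, score: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        if key in seen:
            return
        seen.add(key)
        edges.append(ScoredEdge(key[0], key[1], float(score)))

    for gene, extra in zip(pair_mrnas, config.hub_extra_degrees):
        partners = rng.choice(background_pool, size=extra, replace=False)
        for p in partners:
            add_edge(gene, str(p), rng.uniform(config.ppi_score_threshold, 1.0))
    for _ in range(config.n_background_edges):
        a, b = rng.choice(background_pool, size=2, replace=False)
        add_edge(str(a), str(b), rng.uniform(0.0, 1.0))

    annotations = {l: l in set(annotated_lncs) for l in lncs}
    return edges, sets, categories, annotations


def simulate_phenotypes(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> pd.DataFrame:
    """Per-animal fasting glucose/insulin and tolerance-test time courses.

    Fasting insulin is emitted in uU/mL (the HOMA-IR scale), converted from
    the ng/mL group parameters at 25 uU per ng.
    """
    rng = _rng(config, _STREAM_PHENO)
    rows = []
    for group, size in config.group_sizes.items():
        params = PHENOTYPE_PARAMS.get(group)
        if params is None:
            raise ValueError(f"no phenotype parameters for group {group!r}")
        g_mean, g_sd = params["glucose"]
        i_mean, i_sd = params["insulin_ng"]
        for i in range(size):
            sid = f"{group}_{i + 1:02d}"
            glucose = max(float(rng.normal(g_mean, g_sd)), 40.0)
            insulin_ng = max(float(rng.normal(i_mean, i_sd)), 0.2)
            curve = [
                max(float(rng.normal(mu, 10.0)), 40.0) for mu in params["gtt"]
            ]
            rows.append(
                [sid, group, glucose, insulin_ng * 25.0] + curve
            )
    cols = ["sample", "group", "fasting_glucose", "fasting_insulin"] + [
        f"glucose_{int(t)}" for t in GTT_MINUTES
    ]
    return pd.DataFrame(rows, columns=cols)


def random_noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform-random nucleotides; long ORFs are exponentially unlikely."""
    return "".join(rng.choice(list("ACGT"), size=length))


def coding_like_sequence(
    rng: np.random.Generator, orf_codons: int, flank: int = 50
) -> str:
    """A sequence carrying one clean ATG..stop ORF of ``orf_codons`` codons."""
    non_stop = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
    ]
    body = "".join(rng.choice(non_stop, size=orf_codons - 2))
    orf = "ATG" + body + "TAA"
    return (
        random_noncoding_sequence(rng, flank) + orf
        + random_noncoding_sequence(rng, flank)
    )


def simulate_transcript_fasta(
    config: SimulationConfig, n_records: int = 20
) -> dict[str, str]:
    """Transcript sequences for the ORF-heuristic fallback: planted pair
    lncRNAs get ORF-poor sequences, contaminant-style records a long ORF."""
    from .de_screen import is_coding_by_orf

    rng = _rng(config, _STREAM_FASTA)
    _, lncs = _feature_names(config)
    seqs: dict[str, str] = {}
    for i, l in enumerate(lncs[:n_records]):
        if i % 5 == 4:
            seqs[l] = coding_like_sequence(rng, orf_codons=150)
        else:
            # resample until the draw is genuinely ORF-poor; short random
            # sequences can carry a >=30%-coverage ORF by chance
            for _ in range(100):
                seq = random_noncoding_sequence(rng, int(rng.integers(400, 1200)))
                if not is_coding_by_orf(seq):
                    break
            seqs[l] = seq
    return seqs


def write_fixture_dir(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Emit every pipeline input under ``outdir``; returns paths and truth.

    Files: genome.gtf, mrnas.bed, lncrnas.bed, de_table.tsv,
    coding_potential.tsv, transcripts.fasta, pathways.gmt,
    pathway_categories.tsv, ppi_edges.tsv, lncrna_annotations.tsv,
    ct_table.tsv, phenotypes.tsv, ground_truth.json.  Byte-identical for
    identical config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        name: outdir / fname
        for name, fname in [
            ("gtf", "genome.gtf"),
            ("mrna_bed", "mrnas.bed"),
            ("lncrna_bed", "lncrnas.bed"),
            ("de_table", "de_table.tsv"),
            ("coding_potential", "coding_potential.tsv"),
            ("fasta", "transcripts.fasta"),
            ("gmt", "pathways.gmt"),
            ("categories", "pathway_categories.tsv"),
            ("ppi", "ppi_edges.tsv"),
            ("annotations", "lncrna_annotations.tsv"),
            ("ct_table", "ct_table.tsv"),
            ("phenotypes", "phenotypes.tsv"),
            ("ground_truth", "ground_truth.json"),
        ]
    }
    mrnas, lncs, truth = simulate_genome(config)
    combined = FeatureCatalog(list(mrnas) + list(lncs))
    write_gtf(combined, paths["gtf"])
    write_bed(mrnas, paths["mrna_bed"])
    write_bed(lncs, paths["lncrna_bed"])

    de = simulate_de_table(config, truth)
    de.to_csv(paths["de_table"], sep="\t", index=False, float_format="%.6g")

    cp = simulate_coding_potential(config, truth)
    with open(paths["coding_potential"], "w") as fh:
        fh.write("feature_id\tscore\tlabel\n")
        for r in cp:
            fh.write(f"{r.feature_id}\t{r.score:.4f}\t{r.label}\n")

    seqs = simulate_transcript_fasta(config)
    with open(paths["fasta"], "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    edges, sets, categories, annotations = simulate_ppi_and_sets(config, truth)
    with open(paths["gmt"], "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name] + sorted(gs.members)) + "\n")
    with open(paths["categories"], "w") as fh:
        for set_id, cats in categories.items():
            fh.write(f"{set_id}\t{','.join(sorted(cats))}\n")
    with open(paths["ppi"], "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for e in edges:
            fh.write(f"{e.node_a}\t{e.node_b}\t{int(round(e.score * 1000))}\n")
    with open(paths["annotations"], "w") as fh:
        fh.write("lncrna_id\tannotated\n")
        for l in sorted(annotations):
            fh.write(f"{l}\t{int(annotations[l])}\n")

    ct = simulate_ct_table(config, truth)
    ct.to_tsv(paths["ct_table"])

    pheno = simulate_phenotypes(config, truth)
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.6g")

    truth.to_json(paths["ground_truth"])
    return paths, truth


def random_feature_catalog(
    rng: np.random.Generator,
    n: int,
    feature_class: str,
    n_chroms: int = 5,
    chrom_length: int = 1_000_000,
    length_range: tuple[int, int] = (500, 5_000),
    prefix: str | None = None,
) -> FeatureCatalog:
    """Unstructured random features (overlaps allowed) for oracle tests."""
    prefix = prefix or feature_class
    features = []
    for i in range(n):
        chrom = str(int(rng.integers(1, n_chroms + 1)))
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(0, max(chrom_length - length, 1)))
        features.append(
            GenomicFeature(
                f"{prefix}_{i:05d}", feature_class, chrom, start, start + length,
                "+" if rng.random() < 0.5 else "-",
            )
        )
    return FeatureCatalog(features)


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serializable view of a config (tuple keys flattened)."""
    d = asdict(config)
    d["planted_rho"] = {f"{m}--{l}": r for (m, l), r in config.planted_rho.items()}
    d["pair_names"] = [list(p) for p in config.pair_names]
    d["group_sizes"] = dict(config.group_sizes)
    d["group_effect_multipliers"] = dict(config.group_effect_multipliers)
    d["planted_directions"] = dict(config.planted_directions)
    return d
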