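"""Synthetic hexaploid-style study generator with machine-readable truth.

This module builds a miniature two-species study shaped like a polyploid
wheat gene-family survey: for each simulated family an ancestral lectin
receptor kinase protein is assembled around planted kinase and lectin
domain blocks, copied onto the A, B and D sub-genomes as homoeologs inside
a configured identity band, optionally duplicated on the same chromosome
(tandem, segmental, or onto an unplaced scaffold), and mirrored by a
diverged ortholog in a sister species.  Decoy genes (kinase-only,
lectin-only, unrelated) are planted as negative controls.  Condition-
structured read sets (organs x developmental stages, plus biotic and
abiotic stress contrasts with >=2-fold planted responders) realize known
per-gene abundances.

Every downstream stage has exact ground truth: family classes, domain
intervals, the homolog-cluster partition at the >90% gate, TD/SD/
uncategorized duplication labels at the >=80% gate, reciprocal ortholog
pairs, per-sample per-gene read counts, and fold-change directions.

Design notes
------------
* Mutations are substitutions with exact counts (no indels), so realized
  identities are deterministic; the generator additionally verifies every
  within-family pairwise identity against guard margins around the 90% and
  80% gates (resampling substitution positions when violated) so planted
  truth is unambiguous under alignment-based measurement.
* Domain blocks are protected during copy mutation (classification stays
  intact) but each family's ancestral blocks are themselves diverged ~18%
  from the model consensus, keeping cross-family similarity far below the
  duplication gate.
* Back-translation jitters deterministically between the two most frequent
  codons per residue keyed by (gene id, position), so no two genes share a
  read-length nucleotide k-mer and planted read counts are exactly
  recoverable by exact-match mapping.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import seqio
from .domains import (
    ACCESSORY_DOMAINS,
    KINASE_DOMAIN,
    LECTIN_FAMILY,
    DomainModel,
    load_packaged_models,
)
from .expression import ReadSet, reverse_complement
from .seqio import GeneModel, GenomeSet

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# two most frequent codons per residue (fixed table; single-codon M and W)
_CODONS = {
    "A": ("GCT", "GCC"), "C": ("TGC", "TGT"), "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"), "F": ("TTC", "TTT"), "G": ("GGT", "GGC"),
    "H": ("CAT", "CAC"), "I": ("ATT", "ATC"), "K": ("AAG", "AAA"),
    "L": ("CTT", "CTC"), "M": ("ATG",), "N": ("AAC", "AAT"),
    "P": ("CCT", "CCA"), "Q": ("CAA", "CAG"), "R": ("CGT", "AGG"),
    "S": ("TCT", "AGC"), "T": ("ACT", "ACC"), "V": ("GTT", "GTC"),
    "W": ("TGG",), "Y": ("TAC", "TAT"),
}
_STOP = "TAA"

CLUSTER_GATE = 90.0
DUPLICATION_GATE = 80.0
# realized identities must stay this far on the intended side of each gate
GATE_GUARD = 2.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Identity thresholds mirror the survey design this generator emulates:
    homoeologs above the 90% clustering gate, duplicates above the 80%
    duplication gate, tandem pairs within 5 Mb and segmental pairs beyond
    it on 20 Mb chromosomes.  The expression design is 5 organs x 3 stages
    x 2 replicates plus two biotic (24 h) and six abiotic (heat/drought/
    combined at 1 h and 6 h) stress contrasts.
    """

    seed: int = 7
    n_families: int = 50
    family_mix: tuple[int, int, int] = (16, 32, 2)  # L, B, C families
    homoeolog_identity_range: tuple[float, float] = (93.0, 98.0)
    duplicate_identity_range: tuple[float, float] = (82.0, 95.0)
    n_tandem: int = 5
    n_segmental: int = 8
    n_scaffold_dups: int = 3
    ortholog_divergence: float = 85.0
    n_decoys: int = 12
    block_divergence_pct: float = 18.0
    chromosome_length_bp: int = 20_000_000
    td_window_bp: int = 5_000_000
    organs: tuple[str, ...] = ("root", "stem", "leaf", "spike", "grain")
    stages: tuple[str, ...] = ("Z39", "Z65", "Z85")
    replicates: int = 2
    reads_per_sample: int = 20_000
    read_length: int = 80
    library_total: int = 2_000_000
    n_organ_specific: int = 10
    organ_boost: float = 25.0
    base_abundance_range: tuple[float, float] = (0.8, 2.0)
    up_folds: tuple[float, ...] = (5.0, 3.0)
    down_folds: tuple[float, ...] = (0.2, 0.33)
    special_fold: float = 49.0  # planted in the Bgt-style contrast
    planted_fold_changes: dict | None = None  # gene -> (contrast, fold) overrides

    def __post_init__(self):
        # YAML round-trips sequences as lists; normalize back to tuples
        for name in ("family_mix", "homoeolog_identity_range",
                     "duplicate_identity_range", "organs", "stages",
                     "base_abundance_range", "up_folds", "down_folds"):
            setattr(self, name, tuple(getattr(self, name)))

    def validate(self) -> None:
        if self.homoeolog_identity_range[0] <= CLUSTER_GATE:
            raise ValueError(
                "homoeolog identity band must lie above the 90% clustering gate"
            )
        if self.duplicate_identity_range[0] <= DUPLICATION_GATE:
            raise ValueError(
                "duplicate identity band must lie above the 80% duplication gate"
            )
        if self.n_tandem + self.n_segmental + self.n_scaffold_dups > self.n_families:
            raise ValueError("more planned duplications than families")
        if sum(self.family_mix) != self.n_families:
            raise ValueError("family_mix must sum to n_families")
        if self.read_length < 20:
            raise ValueError("read_length too short for exact-match mapping")


@dataclass
class GroundTruth:
    """Planted truth, consistent with the emitted files byte-for-byte."""

    families: dict[str, str]  # gene -> L_LRK/B_LRK/C_LRK/none
    decoys: set[str]
    domain_intervals: pd.DataFrame  # gene_id, domain_id, start, end
    clusters: list[list[str]]  # partition incl. singletons (species A)
    duplications: pd.DataFrame  # gene_a, gene_b, identity_pct, category, distance_bp
    orthologs: list[tuple[str, str]]  # (species A gene, sister gene)
    nonreciprocal_decoy: str
    homoeolog_triplets: list[tuple[str, str, str]]
    homoeolog_pairs: pd.DataFrame  # gene_a, gene_b, identity_pct (realized)
    counts: pd.DataFrame  # genes x samples realized read counts
    fold_truth: pd.DataFrame  # contrast, gene_id, planted_fold, direction
    contrasts: dict[str, tuple[list[str], list[str]]]
    organ_specific: dict[str, str]

    def cluster_partition(self) -> set[frozenset]:
        return {frozenset(c) for c in self.clusters}

    def responders(self, contrast: str) -> dict[str, str]:
        sub = self.fold_truth[self.fold_truth["contrast"] == contrast]
        return dict(zip(sub["gene_id"], sub["direction"]))


@dataclass
class SimResult:
    config: SimConfig
    genome_a: GenomeSet
    genome_b: GenomeSet
    read_sets: list[ReadSet]
    truth: GroundTruth
    out_dir: Path | None = None


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------


_M64 = (1 << 64) - 1


def _mix64(x: int) -> int:
    # splitmix64 finalizer: non-linear, so per-gene codon choices decorrelate
    # even between ids that differ in a single character
    x &= _M64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _M64
    return x ^ (x >> 31)


def back_translate(protein: str, gene_id: str, stop: bool = True) -> str:
    """Deterministic back-translation with per-gene codon jitter.

    The codon for each residue is chosen between the two most frequent
    codons by a mixed hash of ``gene_id`` and the position, so identical
    protein stretches in different genes still yield diverged transcripts
    (no two genes share a read-length nucleotide k-mer in practice).
    """
    gene_hash = zlib.crc32(gene_id.encode())
    parts = []
    for i, aa in enumerate(protein):
        codons = _CODONS[aa]
        if len(codons) == 1:
            parts.append(codons[0])
        else:
            pick = _mix64((gene_hash << 32) | i) & 1
            parts.append(codons[pick])
    if stop:
        parts.append(_STOP)
    return "".join(parts)


def _pct_identity(a: str, b: str) -> float:
    """Column identity of two equal-length (unaligned) strings."""
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / len(a)


def _substitute(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    chars = list(seq)
    for p in positions:
        old = chars[p]
        choices = [c for c in AA20 if c != old]
        chars[p] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def mutate_to_identity(
    seq: str,
    target_pct: float,
    seed: int | np.random.Generator,
    protected: Sequence[tuple[int, int]] = (),
) -> str:
    """Substitute residues until global identity matches ``target_pct``.

    ``protected`` intervals (1-based inclusive) are never touched, so
    planted domain blocks survive mutation.  The substitution count is
    exact (round((1 - target/100) * len)), so the realized identity is
    within half a percentage point of the target.  Raises if the target is
    unreachable under the protection constraints.
    """
    if not 0 < target_pct <= 100:
        raise ValueError("target_pct must be in (0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = int(round((1.0 - target_pct / 100.0) * len(seq)))
    if n_sub == 0:
        return seq
    blocked = np.zeros(len(seq), dtype=bool)
    for s, e in protected:
        blocked[s - 1 : e] = True
    mutable = np.flatnonzero(~blocked)
    if n_sub > mutable.size:
        raise ValueError(
            f"cannot reach {target_pct}% identity: {n_sub} substitutions "
            f"needed but only {mutable.size} unprotected positions"
        )
    positions = rng.choice(mutable, size=n_sub, replace=False)
    return _substitute(rng, seq, positions)


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list(AA20))[rng.integers(0, 20, size=n)])


def _diverged_block(rng: np.random.Generator, consensus: str, pct: float) -> str:
    n = int(round(pct / 100.0 * len(consensus)))
    pos = rng.choice(len(consensus), size=n, replace=False)
    return _substitute(rng, consensus, pos)


# ---------------------------------------------------------------------------
# family construction
# ---------------------------------------------------------------------------


@dataclass
class _FamilyPlan:
    index: int
    family: str  # L_LRK / B_LRK / C_LRK
    chrom: int
    dup_kind: str | None  # 'TD' | 'SD' | 'scaffold' | None
    ancestor: str = ""
    blocks: list[tuple[str, int, int]] = field(default_factory=list)  # (domain, start, end)
    copies: dict[str, str] = field(default_factory=dict)  # role -> protein
    identities: dict[tuple[str, str], float] = field(default_factory=dict)


_LECTIN_FOR = {"L_LRK": "LEC_LEGUME", "B_LRK": "LEC_BULB", "C_LRK": "LEC_C"}


def _build_ancestor(
    rng: np.random.Generator,
    plan: _FamilyPlan,
    models: Mapping[str, DomainModel],
    block_divergence_pct: float,
) -> None:
    lectin_id = _LECTIN_FOR[plan.family]
    segments: list[tuple[str | None, str]] = []
    segments.append((None, _rand_protein(rng, int(rng.integers(30, 51)))))
    segments.append(
        (lectin_id, _diverged_block(rng, models[lectin_id].consensus, block_divergence_pct))
    )
    segments.append((None, _rand_protein(rng, int(rng.integers(40, 71)))))
    if plan.family == "B_LRK":
        # accessory extracellular domains common in B-type receptors
        if rng.random() < 0.6:
            segments.append(
                ("SLG", _diverged_block(rng, models["SLG"].consensus, block_divergence_pct))
            )
            segments.append((None, _rand_protein(rng, int(rng.integers(10, 26)))))
        if rng.random() < 0.4:
            segments.append(
                ("PAN_APPLE", _diverged_block(rng, models["PAN_APPLE"].consensus, block_divergence_pct))
            )
            segments.append((None, _rand_protein(rng, int(rng.integers(10, 26)))))
    segments.append(
        (KINASE_DOMAIN, _diverged_block(rng, models[KINASE_DOMAIN].consensus, block_divergence_pct))
    )
    segments.append((None, _rand_protein(rng, int(rng.integers(30, 51)))))

    protein = []
    pos = 0
    blocks = []
    for domain, seg in segments:
        if domain is not None:
            blocks.append((domain, pos + 1, pos + len(seg)))
        protein.append(seg)
        pos += len(seg)
    plan.ancestor = "".join(protein)
    plan.blocks = blocks


def _draw_in_band(rng: np.random.Generator, lo: float, hi: float) -> float:
    # keep away from the band edges so exact substitution rounding stays inside
    return float(rng.uniform(lo + 0.2, hi - 0.2))


def _draw_duplicate_identity(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Duplicate identity from (lo, hi) excluding a guard zone around 90%."""
    low_band = (lo + 0.2, min(hi, CLUSTER_GATE - 2.5))
    high_band = (CLUSTER_GATE + 2.5, hi - 0.2)
    bands = [b for b in (low_band, high_band) if b[1] > b[0]]
    widths = np.array([b[1] - b[0] for b in bands])
    pick = bands[int(rng.choice(len(bands), p=widths / widths.sum()))]
    return float(rng.uniform(*pick))


def _mutate_copy(
    rng: np.random.Generator,
    plan: _FamilyPlan,
    target: float,
    forbid: Iterable[int] = (),
) -> str:
    """Mutated copy of the ancestor; ``forbid`` lists extra 0-based
    positions to leave untouched (used to keep scaffold-duplicate
    identities to the other copies deterministically low)."""
    protected = [(s, e) for _, s, e in plan.blocks]
    protected += [(p + 1, p + 1) for p in forbid]
    return mutate_to_identity(plan.ancestor, target, rng, protected)


def _diff_positions(a: str, b: str) -> set[int]:
    return {i for i, (x, y) in enumerate(zip(a, b)) if x != y}


def _family_guards_ok(plan: _FamilyPlan) -> bool:
    """Check realized identities against gate guard margins.

    Pairs intended above a gate must be >= gate + guard is not required
    (being above is enough since alignment identity can only nudge
    upward); pairs intended below must sit at least GATE_GUARD under it.
    """
    roles = list(plan.copies)
    for i, r1 in enumerate(roles):
        for r2 in roles[i + 1 :]:
            ident = _pct_identity(plan.copies[r1], plan.copies[r2])
            plan.identities[(r1, r2)] = ident
            # clustering gate: anything not meant to cluster must stay low
            if ident <= CLUSTER_GATE and ident > CLUSTER_GATE - 1.5:
                return False
            # duplication gate: only same-chromosome / scaffold pairs are
            # event candidates, but guard every pair for simplicity
            if DUPLICATION_GATE - GATE_GUARD < ident < DUPLICATION_GATE:
                return False
    return True


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig | None = None, out_dir: str | Path | None = None) -> SimResult:
    """Generate the two-species study; optionally serialize it to disk.

    Returns genomes, read sets and :class:`GroundTruth`.  Fully
    deterministic under ``cfg.seed`` (byte-identical files on re-run).
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    models = load_packaged_models()

    # --- family plans -----------------------------------------------------
    classes = (
        ["L_LRK"] * cfg.family_mix[0]
        + ["B_LRK"] * cfg.family_mix[1]
        + ["C_LRK"] * cfg.family_mix[2]
    )
    dup_kinds: list[str | None] = (
        ["TD"] * cfg.n_tandem
        + ["SD"] * cfg.n_segmental
        + ["scaffold"] * cfg.n_scaffold_dups
        + [None] * (cfg.n_families - cfg.n_tandem - cfg.n_segmental - cfg.n_scaffold_dups)
    )
    dup_kinds = list(np.asarray(dup_kinds, dtype=object)[rng.permutation(cfg.n_families)])

    plans = [
        _FamilyPlan(index=i, family=classes[i], chrom=(i % 7) + 1, dup_kind=dup_kinds[i])
        for i in range(cfg.n_families)
    ]

    h_lo, h_hi = cfg.homoeolog_identity_range
    d_lo, d_hi = cfg.duplicate_identity_range
    for plan in plans:
        _build_ancestor(rng, plan, models, cfg.block_divergence_pct)
        for attempt in range(60):
            plan.copies = {"A": plan.ancestor}
            if plan.dup_kind == "scaffold":
                # keep the scaffold copy's cross-identities clear of 80%
                t_b = float(rng.uniform(93.0, 94.0))
                t_d = float(rng.uniform(93.0, 94.0))
                t_dup = float(rng.uniform(82.2, 83.0))
            else:
                t_b = _draw_in_band(rng, h_lo, h_hi)
                t_d = _draw_in_band(rng, h_lo, h_hi)
                t_dup = _draw_duplicate_identity(rng, d_lo, d_hi)
            plan.copies["B"] = _mutate_copy(rng, plan, t_b)
            plan.copies["D"] = _mutate_copy(rng, plan, t_d)
            if plan.dup_kind is not None:
                forbid: set[int] = set()
                if plan.dup_kind == "scaffold":
                    # disjoint substitution sets pin the scaffold copy's
                    # identity to B/D at 100 - (d_dup + d_homoeolog) < 78
                    forbid = _diff_positions(plan.ancestor, plan.copies["B"])
                    forbid |= _diff_positions(plan.ancestor, plan.copies["D"])
                plan.copies["dup"] = _mutate_copy(rng, plan, t_dup, forbid)
            plan.copies["ortholog"] = _mutate_copy(
                rng, plan, float(rng.uniform(cfg.ortholog_divergence - 1, cfg.ortholog_divergence + 1))
            )
            plan.identities = {}
            if _family_guards_ok(plan) and _ortholog_guard_ok(plan):
                break
        else:
            raise RuntimeError(
                f"family {plan.index}: could not satisfy identity guards"
            )

    # --- gene models, ids, coordinates ------------------------------------
    genome_a = GenomeSet(species_label="speciesA")
    genome_b = GenomeSet(species_label="speciesB")
    serial = 0
    scaffold_serial = 1000
    families: dict[str, str] = {}
    decoys: set[str] = set()
    domain_rows = []
    clusters: list[list[str]] = []
    dup_rows = []
    orthologs: list[tuple[str, str]] = []
    triplets: list[tuple[str, str, str]] = []
    pair_rows = []

    def _make_id(chrom: int, sub: str, start: int) -> str:
        nonlocal serial
        serial += 1
        arm = "S" if start < cfg.chromosome_length_bp // 2 else "L"
        return f"Traes_{chrom}{sub}{arm}_{serial:04d}"

    def _exon_plan(fam: str, cds_len: int, start: int) -> tuple[tuple[tuple[int, int], ...], int]:
        if fam == "C_LRK":
            n_exons = 4
        else:
            r = rng.random()
            n_exons = 1 if r < 0.7 else (2 if r < 0.9 else 3)
        if n_exons == 1:
            return ((start, start + cds_len - 1),), start + cds_len - 1
        cuts = np.sort(rng.choice(np.arange(1, cds_len // 3), size=n_exons - 1, replace=False)) * 3
        seg_lens = np.diff(np.concatenate(([0], cuts, [cds_len])))
        exons = []
        pos = start
        for k, L in enumerate(seg_lens):
            exons.append((pos, pos + int(L) - 1))
            pos += int(L)
            if k < len(seg_lens) - 1:
                pos += int(rng.integers(80, 301))
        return tuple(exons), exons[-1][1]

    def _add_gene(genome: GenomeSet, gene_id: str, protein: str, chrom_label, start: int,
                  fam: str, blocks=None, exon_fam: str = "") -> GeneModel:
        cds = back_translate(protein, gene_id)
        exons, end = _exon_plan(exon_fam or fam, len(cds), start)
        strand = "+" if rng.random() < 0.5 else "-"
        g = GeneModel.from_parts(
            gene_id=gene_id, start=start, end=end, strand=strand,
            exons=exons, cds=cds, protein=protein, stop_included=True,
        )
        genome.add(g)
        families[gene_id] = fam
        if blocks:
            for domain, s, e in blocks:
                domain_rows.append(
                    {"gene_id": gene_id, "domain_id": domain, "start": s, "end": e}
                )
        return g

    half = cfg.chromosome_length_bp // 2
    for plan in plans:
        c = plan.chrom
        # A copy placed in the first quarter so TD/SD partners fit downstream
        a_start = int(rng.integers(500_000, 4_000_000))
        a_id = _make_id(c, "A", a_start)
        _add_gene(genome_a, a_id, plan.copies["A"], f"{c}A", a_start, plan.family, plan.blocks)

        b_start = int(rng.integers(500_000, cfg.chromosome_length_bp - 100_000))
        b_id = _make_id(c, "B", b_start)
        _add_gene(genome_a, b_id, plan.copies["B"], f"{c}B", b_start, plan.family, plan.blocks)

        d_start = int(rng.integers(500_000, cfg.chromosome_length_bp - 100_000))
        d_id = _make_id(c, "D", d_start)
        _add_gene(genome_a, d_id, plan.copies["D"], f"{c}D", d_start, plan.family, plan.blocks)

        triplets.append((a_id, b_id, d_id))
        pair_rows.append({"gene_a": a_id, "gene_b": b_id,
                          "identity_pct": plan.identities[("A", "B")]})
        pair_rows.append({"gene_a": a_id, "gene_b": d_id,
                          "identity_pct": plan.identities[("A", "D")]})

        cluster = [a_id, b_id, d_id]
        dup_id = None
        if plan.dup_kind is not None:
            ident_dup = plan.identities[("A", "dup")]
            if plan.dup_kind == "TD":
                dstart = a_start + int(rng.integers(300_000, cfg.td_window_bp - 1_200_000))
                dup_id = _make_id(c, "A", dstart)
                _add_gene(genome_a, dup_id, plan.copies["dup"], f"{c}A", dstart,
                          plan.family, plan.blocks)
                dup_rows.append({"gene_a": min(a_id, dup_id), "gene_b": max(a_id, dup_id),
                                 "identity_pct": ident_dup, "category": "TD",
                                 "distance_bp": dstart - a_start})
            elif plan.dup_kind == "SD":
                dstart = a_start + int(rng.integers(cfg.td_window_bp + 3_000_000, 15_000_000))
                dup_id = _make_id(c, "A", dstart)
                _add_gene(genome_a, dup_id, plan.copies["dup"], f"{c}A", dstart,
                          plan.family, plan.blocks)
                dup_rows.append({"gene_a": min(a_id, dup_id), "gene_b": max(a_id, dup_id),
                                 "identity_pct": ident_dup, "category": "SD",
                                 "distance_bp": dstart - a_start})
            else:  # scaffold
                scaffold_serial += 1
                dup_id = f"scaffold_{scaffold_serial}_g1"
                _add_gene(genome_a, dup_id, plan.copies["dup"], None, 1_000,
                          plan.family, plan.blocks)
                dup_rows.append({"gene_a": min(a_id, dup_id), "gene_b": max(a_id, dup_id),
                                 "identity_pct": ident_dup, "category": "uncategorized",
                                 "distance_bp": -1})
            if ident_dup > CLUSTER_GATE:
                cluster.append(dup_id)
            else:
                clusters.append([dup_id])
        clusters.append(sorted(cluster))

        o_id = f"SisLRK_{plan.index + 1:03d}"
        _add_gene(genome_b, o_id, plan.copies["ortholog"], None, 1_000, plan.family, plan.blocks)
        orthologs.append((a_id, o_id))

    # --- decoys ------------------------------------------------------------
    n_each = cfg.n_decoys // 3
    for k in range(cfg.n_decoys):
        kind = "kinase" if k < n_each else ("lectin" if k < 2 * n_each else "random")
        on_scaffold = k % 5 == 4
        if kind == "kinase":
            blk = _diverged_block(rng, models[KINASE_DOMAIN].consensus, cfg.block_divergence_pct)
            prot = (_rand_protein(rng, int(rng.integers(60, 120))) + blk
                    + _rand_protein(rng, int(rng.integers(40, 90))))
        elif kind == "lectin":
            lid = ("LEC_LEGUME", "LEC_BULB", "LEC_C")[k % 3]
            blk = _diverged_block(rng, models[lid].consensus, cfg.block_divergence_pct)
            prot = (_rand_protein(rng, int(rng.integers(60, 120))) + blk
                    + _rand_protein(rng, int(rng.integers(40, 90))))
        else:
            prot = _rand_protein(rng, int(rng.integers(250, 330)))
        if on_scaffold:
            scaffold_serial += 1
            gid = f"scaffold_{scaffold_serial}_g1"
            start = 1_000
        else:
            chrom = int(rng.integers(1, 8))
            sub = "ABD"[int(rng.integers(3))]
            start = int(rng.integers(500_000, cfg.chromosome_length_bp - 100_000))
            gid = _make_id(chrom, sub, start)
        _add_gene(genome_a, gid, prot, None, start, "none")
        decoys.add(gid)
        clusters.append([gid])

    # non-reciprocal sister decoy: diverged second copy of family 0's A gene
    plan0 = plans[0]
    decoy_prot = None
    for _ in range(40):
        cand = _mutate_copy(rng, plan0, 80.0)
        best = _pct_identity(cand, plan0.copies["A"])
        others = [_pct_identity(cand, plan0.copies[r]) for r in ("B", "D")]
        o_vs_a = plan0.identities[("A", "ortholog")]
        if best < o_vs_a - 1.5 and all(best > o + 1.5 for o in others):
            decoy_prot = cand
            break
    if decoy_prot is None:  # pragma: no cover - guards are generous
        raise RuntimeError("could not build the non-reciprocal sister decoy")
    nr_id = "SisLRK_900"
    _add_gene(genome_b, nr_id, decoy_prot, None, 1_000, plan0.family, plan0.blocks)

    # --- expression design -------------------------------------------------
    read_sets, counts_df, fold_df, contrasts, organ_specific = _simulate_expression(
        rng, cfg, genome_a, families, decoys
    )

    truth = GroundTruth(
        families=families,
        decoys=decoys,
        domain_intervals=pd.DataFrame(domain_rows),
        clusters=sorted(clusters),
        duplications=pd.DataFrame(dup_rows).sort_values(
            ["gene_a", "gene_b"], ignore_index=True
        ),
        orthologs=sorted(orthologs),
        nonreciprocal_decoy=nr_id,
        homoeolog_triplets=triplets,
        homoeolog_pairs=pd.DataFrame(pair_rows),
        counts=counts_df,
        fold_truth=fold_df,
        contrasts=contrasts,
        organ_specific=organ_specific,
    )
    result = SimResult(cfg, genome_a, genome_b, read_sets, truth)
    if out_dir is not None:
        result.out_dir = Path(out_dir)
        _serialize(result)
    return result


def _ortholog_guard_ok(plan: _FamilyPlan) -> bool:
    """The sister copy must be closest to the A copy by a clear margin."""
    o = plan.copies["ortholog"]
    best = _pct_identity(o, plan.copies["A"])
    plan.identities[("A", "ortholog")] = best
    for role in ("B", "D", "dup"):
        if role in plan.copies and role != "A":
            if best < _pct_identity(o, plan.copies[role]) + 1.5:
                return False
    return True


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


def _simulate_expression(
    rng: np.random.Generator,
    cfg: SimConfig,
    genome_a: GenomeSet,
    families: Mapping[str, str],
    decoys: set[str],
):
    genes = [g.gene_id for g in genome_a]
    lrk_genes = [g for g in genes if families[g] != "none"]
    lo, hi = cfg.base_abundance_range
    base = {g: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for g in genes}

    # organ-specific genes
    organ_specific: dict[str, str] = {}
    pool = list(lrk_genes)
    n_specific = min(cfg.n_organ_specific, max(len(pool) - 5, 0))
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_specific, replace=False)]
    for i, g in enumerate(chosen):
        organ_specific[g] = cfg.organs[i % len(cfg.organs)]

    # stress contrasts: two biotic at 24 h, heat/drought/combined at 1 h and 6 h
    contrasts: dict[str, tuple[list[str], list[str]]] = {}
    reps = range(1, cfg.replicates + 1)
    for stress in ("Bgt", "Pst"):
        contrasts[f"{stress}_24h"] = (
            [f"{stress}_24h_r{r}" for r in reps],
            [f"mock_24h_r{r}" for r in reps],
        )
    for stress in ("HS", "DS", "HD"):
        for tp in ("1h", "6h"):
            contrasts[f"{stress}_{tp}"] = (
                [f"{stress}_{tp}_r{r}" for r in reps],
                [f"mock_{tp}_r{r}" for r in reps],
            )

    # planted responders: distinct genes per contrast, clear of the 2x gate
    fold_rows = []
    planted: dict[str, dict[str, float]] = {c: {} for c in contrasts}
    if cfg.planted_fold_changes:
        for gene, (contrast, fold) in cfg.planted_fold_changes.items():
            planted[contrast][gene] = float(fold)
    else:
        import itertools

        avail = [g for g in lrk_genes if g not in organ_specific]
        order = [avail[i] for i in rng.permutation(len(avail))]
        it = itertools.cycle(order)  # small genomes reuse genes across contrasts
        for contrast in contrasts:
            folds = list(cfg.up_folds) + list(cfg.down_folds)
            if contrast == "Bgt_24h":
                folds.append(cfg.special_fold)
            for f in folds:
                gene = next(it)
                while gene in planted[contrast]:
                    gene = next(it)
                planted[contrast][gene] = f
    for contrast, mapping in planted.items():
        for gene, f in mapping.items():
            direction = "up" if f >= 2.0 else ("down" if f <= 0.5 else "unaffected")
            fold_rows.append(
                {"contrast": contrast, "gene_id": gene, "planted_fold": f,
                 "direction": direction}
            )
            # boost the control-side abundance so both sides are well sampled
            base[gene] *= 6.0 if f <= 0.5 else 3.0

    scale = cfg.reads_per_sample / sum(base.values())

    def _sample(sample_id: str, mean_of, organ="", stage="", stress="", tp="", rep=1) -> tuple[ReadSet, dict[str, int]]:
        counts = {}
        reads = []
        n = 0
        for g in genes:
            gene = genome_a.genes[g]
            mu = mean_of(g) * scale
            c = int(rng.poisson(mu))
            counts[g] = c
            if c == 0:
                continue
            t = gene.cds
            span = len(t) - cfg.read_length
            starts = rng.integers(0, span + 1, size=c)
            flips = rng.random(c) < 0.5
            for s, flip in zip(starts, flips):
                frag = t[int(s) : int(s) + cfg.read_length]
                reads.append(reverse_complement(frag) if flip else frag)
            n += c
        rs = ReadSet(
            sample_id=sample_id, organ=organ, stage=stage, stress=stress,
            timepoint=tp, replicate=rep, reads=reads,
            library_total=cfg.library_total,
        )
        return rs, counts

    read_sets: list[ReadSet] = []
    count_cols: dict[str, dict[str, int]] = {}

    stage_mult = (0.8, 1.0, 1.25)
    for organ in cfg.organs:
        for si, stage in enumerate(cfg.stages):
            for rep in reps:
                sid = f"{organ}_{stage}_r{rep}"

                def mean_of(g, _o=organ, _si=si):
                    m = base[g] * stage_mult[(hash_stable(g) + _si) % 3]
                    if organ_specific.get(g) == _o:
                        m *= cfg.organ_boost
                    return m

                rs, counts = _sample(sid, mean_of, organ=organ, stage=stage, rep=rep)
                read_sets.append(rs)
                count_cols[sid] = counts

    stress_samples = ["mock_24h", "Bgt_24h", "Pst_24h", "mock_1h", "mock_6h",
                      "HS_1h", "HS_6h", "DS_1h", "DS_6h", "HD_1h", "HD_6h"]
    for name in stress_samples:
        stress, tp = name.rsplit("_", 1)
        contrast = name if name in contrasts else ""
        for rep in reps:
            sid = f"{name}_r{rep}"

            def mean_of(g, _contrast=contrast):
                m = base[g]
                if _contrast and g in planted[_contrast]:
                    m *= planted[_contrast][g]
                return m

            rs, counts = _sample(sid, mean_of, organ="leaf", stage="seedling",
                                 stress=stress, tp=tp, rep=rep)
            read_sets.append(rs)
            count_cols[sid] = counts

    counts_df = pd.DataFrame(count_cols, index=genes)
    fold_df = pd.DataFrame(fold_rows)
    return read_sets, counts_df, fold_df, contrasts, organ_specific


def hash_stable(s: str) -> int:
    """Deterministic small hash (CRC32) used for reproducible per-gene texture."""
    return zlib.crc32(s.encode())


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _serialize(result: SimResult) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    ga, gb, truth = result.genome_a, result.genome_b, result.truth

    seqio.write_fasta(ga.proteins(), out / "speciesA.protein.fa")
    seqio.write_fasta(ga.transcripts(), out / "speciesA.cds.fa")
    seqio.write_gff3(ga, out / "speciesA.gff3")
    seqio.write_fasta(gb.proteins(), out / "speciesB.protein.fa")
    seqio.write_fasta(gb.transcripts(), out / "speciesB.cds.fa")

    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    qual = "I" * result.config.read_length
    sample_rows = []
    for rs in result.read_sets:
        with open(reads_dir / f"{rs.sample_id}.fq", "w") as fh:
            for i, r in enumerate(rs.reads):
                fh.write(f"@{rs.sample_id}.{i + 1}\n{r}\n+\n{qual}\n")
        sample_rows.append(rs.meta_row())
    pd.DataFrame(sample_rows).to_csv(out / "samples.tsv", sep="\t", index=False)

    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    fam_df = pd.DataFrame(
        [{"gene_id": g, "family": f, "is_decoy": int(g in truth.decoys)}
         for g, f in truth.families.items()]
    )
    cluster_df = pd.DataFrame(
        [{"cluster_index": i + 1, "gene_id": m}
         for i, c in enumerate(truth.clusters) for m in c]
    )
    ortho_df = pd.DataFrame(truth.orthologs, columns=["gene_species1", "gene_species2"])
    tables = {
        "families": fam_df,
        "domains": truth.domain_intervals,
        "clusters": cluster_df,
        "duplications": truth.duplications,
        "orthologs": ortho_df,
        "homoeolog_pairs": truth.homoeolog_pairs,
        "fold_changes": truth.fold_truth,
        "organ_specific": pd.DataFrame(
            [{"gene_id": g, "organ": o} for g, o in truth.organ_specific.items()]
        ),
    }
    for name, df in tables.items():
        df.to_csv(tdir / f"{name}.tsv", sep="\t", index=False)
    truth.counts.rename_axis("gene_id").to_csv(tdir / "counts.tsv", sep="\t")
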