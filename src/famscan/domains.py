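"""Domain scanning and lectin-receptor-kinase family classification.

A lectin receptor kinase (LRK) couples an extracellular lectin domain to a
cytoplasmic Ser/Thr protein-kinase domain.  The family class follows from
the lectin type found next to the kinase domain:

* legume-type lectin + kinase  -> L-LRK
* bulb/GNA-type (B-) lectin + kinase -> B-LRK
* calcium-dependent (C-) lectin + kinase -> C-LRK

Accessory S-locus glycoprotein and PAN/APPLE domains are commonly found in
B-LRKs; they are kept as evidence but never change the class.  A protein
with a kinase but no lectin (or a lectin but no kinase) is not an LRK.

Domain models here are small position-specific scoring matrices (PSSMs)
shipped as plain-text files under ``famscan/data/pssm``.  They are scaled-
down stand-ins adequate for synthetic and consensus-like sequences; for real
proteomes a pre-computed domain-hit TSV (e.g. converted hmmscan output) can
be supplied instead of running :func:`scan_domains`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

#: Alphabet used by PSSM columns (20 standard residues, alphabetical).
PSSM_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_PSSM_CODE = {c: i for i, c in enumerate(PSSM_ALPHABET)}

KINASE_DOMAIN = "PKINASE"
LECTIN_FAMILY = {"LEC_LEGUME": "L_LRK", "LEC_BULB": "B_LRK", "LEC_C": "C_LRK"}
ACCESSORY_DOMAINS = ("SLG", "PAN_APPLE")
FAMILIES = ("L_LRK", "B_LRK", "C_LRK", "none")


@dataclass
class DomainModel:
    """A positional log-odds model for one domain.

    ``pssm`` is an L x 20 matrix over :data:`PSSM_ALPHABET`; a window scores
    the sum of its per-position entries and is a hit at ``min_score`` or
    above.
    """

    domain_id: str
    pssm: np.ndarray
    min_score: float

    def __post_init__(self):
        self.pssm = np.asarray(self.pssm, dtype=np.float64)
        if self.pssm.ndim != 2 or self.pssm.shape[1] != len(PSSM_ALPHABET):
            raise ValueError("pssm must be L x 20")
        if self.pssm.shape[0] < 5:
            raise ValueError("domain model too short (L >= 5 required)")
        if not np.isfinite(self.min_score):
            raise ValueError("min_score must be finite")

    @property
    def length(self) -> int:
        return self.pssm.shape[0]

    # canonical_length in the sense of the model's own extent
    canonical_length = length

    @property
    def consensus(self) -> str:
        """Highest-scoring residue at each position."""
        return "".join(PSSM_ALPHABET[i] for i in self.pssm.argmax(axis=1))

    def self_score(self) -> float:
        """Score of the consensus sequence against the model."""
        return float(self.pssm.max(axis=1).sum())


def pssm_from_consensus(
    domain_id: str,
    consensus: str,
    match: float = 5.0,
    mismatch: float = -2.0,
    min_score_frac: float = 0.6,
) -> DomainModel:
    """Build a simple consensus-anchored PSSM.

    The consensus residue scores ``match`` at its position, everything else
    ``mismatch``; the hit threshold defaults to 60% of the consensus
    self-score, which tolerates moderately diverged family members while
    rejecting shuffled sequence.
    """
    L = len(consensus)
    pssm = np.full((L, len(PSSM_ALPHABET)), mismatch, dtype=np.float64)
    for i, c in enumerate(consensus):
        pssm[i, _PSSM_CODE[c]] = match
    min_score = min_score_frac * match * L
    return DomainModel(domain_id, pssm, min_score)


def save_pssm(model: DomainModel, path: str | Path) -> None:
    """Write a model in the text format read by :func:`load_pssm`."""
    with open(path, "w") as fh:
        fh.write("# famscan PSSM v1\n")
        fh.write(f"id\t{model.domain_id}\n")
        fh.write(f"length\t{model.length}\n")
        fh.write(f"min_score\t{model.min_score:g}\n")
        fh.write("alphabet\t" + PSSM_ALPHABET + "\n")
        for i in range(model.length):
            row = "\t".join(f"{v:g}" for v in model.pssm[i])
            fh.write(f"{i + 1}\t{row}\n")


def load_pssm(source) -> DomainModel:
    """Read a model from a path or open text handle."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    for line in lines:
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] in ("id", "length", "min_score", "alphabet"):
            meta[parts[0]] = parts[1]
        else:
            rows.append([float(v) for v in parts[1:]])
    if meta.get("alphabet", PSSM_ALPHABET) != PSSM_ALPHABET:
        raise ValueError("unsupported PSSM alphabet")
    pssm = np.array(rows, dtype=np.float64)
    if int(meta["length"]) != pssm.shape[0]:
        raise ValueError("PSSM length header does not match row count")
    return DomainModel(meta["id"], pssm, float(meta["min_score"]))


def load_packaged_models() -> dict[str, DomainModel]:
    """Load the PSSMs shipped with the package, keyed by domain id."""
    models = {}
    root = resources.files("famscan").joinpath("data/pssm")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".pssm"):
            m = load_pssm(entry.open("r"))
            models[m.domain_id] = m
    return models


# ---------------------------------------------------------------------------
# Scanning and classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainHit:
    """One domain occurrence on a protein (1-based inclusive AA interval)."""

    gene_id: str
    domain_id: str
    start: int
    end: int
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FamilyAssignment:
    gene_id: str
    family: str  # one of FAMILIES
    evidence: list[DomainHit]
    ambiguous: bool = False


def _encode_pssm(protein: str) -> np.ndarray:
    out = np.full(len(protein), -1, dtype=np.int64)
    for i, c in enumerate(protein):
        out[i] = _PSSM_CODE.get(c, -1)
    return out


def scan_domains(
    protein: str,
    models: Mapping[str, DomainModel],
    gene_id: str = "",
) -> list[DomainHit]:
    """Slide every model over the protein and report threshold-passing hits.

    Overlapping hits of the same domain are merged keeping the best-scoring
    window.  Hits are sorted by start position.  A protein shorter than a
    model simply cannot hit it (no error).
    """
    if not models:
        raise ValueError("no domain models supplied")
    enc = _encode_pssm(protein)
    hits: list[DomainHit] = []
    n = len(enc)
    for model in models.values():
        L = model.length
        if n < L:
            continue
        # score every window: residues outside the PSSM alphabet (e.g. X)
        # contribute the column minimum
        colmin = model.pssm.min(axis=1)
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        pos = np.arange(L)
        scores = np.where(
            windows >= 0,
            model.pssm[pos[None, :], np.clip(windows, 0, None)],
            colmin[None, :],
        ).sum(axis=1)
        above = np.flatnonzero(scores >= model.min_score)
        if above.size == 0:
            continue
        # merge runs of overlapping windows, keep the best window of each run
        run_best = above[0]
        run_end = above[0]
        merged = []
        for idx in above[1:]:
            if idx <= run_end + L - 1:  # overlaps current run
                if scores[idx] > scores[run_best]:
                    run_best = idx
                run_end = idx
            else:
                merged.append(run_best)
                run_best = idx
                run_end = idx
        merged.append(run_best)
        for idx in merged:
            hits.append(
                DomainHit(
                    gene_id=gene_id,
                    domain_id=model.domain_id,
                    start=int(idx) + 1,
                    end=int(idx) + L,
                    score=float(scores[idx]),
                )
            )
    hits.sort(key=lambda h: (h.start, h.domain_id))
    return hits


def classify_family(hits: Sequence[DomainHit], gene_id: str = "") -> FamilyAssignment:
    """Apply the kinase + lectin co-occurrence rule to one protein's hits.

    A single kinase hit together with at least one lectin hit assigns the
    class matching the lectin type.  Accessory SLG/PAN hits ride along as
    evidence.  If two different lectin types co-occur with a kinase the
    higher-scoring lectin decides and the assignment is flagged ambiguous.
    """
    if not gene_id:
        gene_id = hits[0].gene_id if hits else ""
    kinase = [h for h in hits if h.domain_id == KINASE_DOMAIN]
    lectins = [h for h in hits if h.domain_id in LECTIN_FAMILY]
    if not kinase or not lectins:
        return FamilyAssignment(gene_id, "none", list(hits))
    types = {h.domain_id for h in lectins}
    ambiguous = len(types) > 1
    if ambiguous:
        best = max(lectins, key=lambda h: h.score)
        warnings.warn(
            f"{gene_id or 'protein'}: multiple lectin types "
            f"{sorted(types)}; classifying by the higher-scoring "
            f"{best.domain_id}",
            stacklevel=2,
        )
        family = LECTIN_FAMILY[best.domain_id]
    else:
        family = LECTIN_FAMILY[types.pop()]
    # evidence: the single best kinase hit plus all lectin/accessory hits
    best_kinase = max(kinase, key=lambda h: h.score)
    evidence = [best_kinase] + [h for h in hits if h.domain_id != KINASE_DOMAIN]
    evidence.sort(key=lambda h: (h.start, h.domain_id))
    return FamilyAssignment(gene_id, family, evidence, ambiguous)


def classify_proteins(
    proteins: Mapping[str, str],
    models: Mapping[str, DomainModel],
) -> dict[str, FamilyAssignment]:
    """Scan and classify a whole protein set (insertion order preserved)."""
    out = {}
    for gid, seq in proteins.items():
        out[gid] = classify_family(scan_domains(seq, models, gid), gid)
    return out


# ---------------------------------------------------------------------------
# Protein descriptors
# ---------------------------------------------------------------------------

# EMBOSS-style pKa values: side chains and termini.
_PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def net_charge(protein: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a peptide at the given pH."""
    pos = 1.0 / (1.0 + 10.0 ** (ph - _PKA_POSITIVE["nterm"]))
    neg = 1.0 / (1.0 + 10.0 ** (_PKA_NEGATIVE["cterm"] - ph))
    for aa in protein:
        if aa in _PKA_POSITIVE:
            pos += 1.0 / (1.0 + 10.0 ** (ph - _PKA_POSITIVE[aa]))
        elif aa in _PKA_NEGATIVE:
            neg += 1.0 / (1.0 + 10.0 ** (_PKA_NEGATIVE[aa] - ph))
    return pos - neg


def compute_mw_pi(protein: str, tol: float = 0.01) -> tuple[float, float]:
    """Average-mass molecular weight (Da) and isoelectric point.

    MW uses average residue masses plus one water.  pI is found by bisection
    on the net-charge curve to ``tol`` pH units using a fixed EMBOSS-style
    pKa table.  Non-standard residues (including X) are rejected.
    """
    bad = [c for c in protein if c not in _STANDARD]
    if bad:
        raise ValueError(f"non-standard residue {bad[0]!r} in protein")
    mw = ProteinAnalysis(protein).molecular_weight()
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return float(mw), 0.5 * (lo + hi)


def domain_length_stats(assignments: Iterable[FamilyAssignment]) -> pd.DataFrame:
    """Per-family mean lectin and kinase domain lengths (AA).

    Families with no classified member are omitted; the table mirrors the
    'major domains average size' style of family summaries.
    """
    acc: dict[str, dict[str, list[int]]] = {}
    for a in assignments:
        if a.family == "none":
            continue
        slot = acc.setdefault(a.family, {"lectin": [], "kinase": []})
        for h in a.evidence:
            if h.domain_id == KINASE_DOMAIN:
                slot["kinase"].append(h.length)
            elif h.domain_id in LECTIN_FAMILY:
                slot["lectin"].append(h.length)
    rows = []
    for family in ("L_LRK", "B_LRK", "C_LRK"):
        if family not in acc:
            continue
        rows.append(
            {
                "family": family,
                "mean_lectin_len": float(np.mean(acc[family]["lectin"])) if acc[family]["lectin"] else float("nan"),
                "mean_kinase_len": float(np.mean(acc[family]["kinase"])) if acc[family]["kinase"] else float("nan"),
                "n_members": sum(1 for _ in acc[family]["kinase"]),
            }
        )
    return pd.DataFrame(rows)


def hits_to_table(hits: Iterable[DomainHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.gene_id, h.domain_id, h.start, h.end, h.score) for h in hits],
        columns=["gene_id", "domain_id", "start", "end", "score"],
    )


def hits_from_table(df: pd.DataFrame) -> dict[str, list[DomainHit]]:
    """Group a (gene_id, domain_id, start, end, score) table per gene.

    This is the bring-your-own-scanner path: any tool whose output is
    converted to this five-column TSV can replace :func:`scan_domains`.
    """
    out: dict[str, list[DomainHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, []).append(
            DomainHit(row.gene_id, row.domain_id, int(row.start), int(row.end), float(row.score))
        )
    return out
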