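"""Quality control, dereplication and abundance linking of organellar MAGs.

Completeness and redundancy from single-copy marker-gene complements,
contamination screening of plastid bins against mitochondrial markers,
single-linkage ANI dereplication with reference-first representative
selection, a k-mer sketch ANI estimator, the coverage detection rule
(mean coverage zeroed where less than a quarter of the genome is covered),
and ordinary-least-squares coverage-correlation linking of organelle pairs.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DETECTION_CUTOFF = 0.25


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise QCError("marker set must contain at least one gene")
        if len(set(g.lower() for g in self.genes)) != len(self.genes):
            raise QCError("duplicate marker genes")

    @property
    def size(self) -> int:
        return len(self.genes)


def _load_list(filename: str) -> tuple[str, ...]:
    text = (resources.files("leptokit.data") / filename).read_text()
    return tuple(ln.strip() for ln in text.splitlines() if ln.strip())


def plastid_core_markers() -> MarkerSet:
    """The 44-gene plastid core used for completeness/redundancy (editable
    default list shipped with the package)."""
    return MarkerSet("plastid_core", _load_list("plastid_core_genes.txt"))


def mito_screen_markers() -> MarkerSet:
    """The 25-gene canonical mitochondrial screen for contamination checks."""
    return MarkerSet("mito_screen", _load_list("mito_screen_genes.txt"))


@dataclass
class QCReport:
    genome: str
    completeness: float     # percent of markers present at least once
    redundancy: float       # percent of extra marker copies
    near_complete: bool
    copy_counts: dict[str, int]
    unknown_genes: list[str] = field(default_factory=list)


def completeness_redundancy(gene_copies: dict[str, int], markers: MarkerSet,
                            genome: str = "genome",
                            near_complete_min: int = 40) -> QCReport:
    """Marker-based completeness and redundancy of one genome.

    completeness = 100 * (markers present) / |markers|;
    redundancy = 100 * sum(max(0, copies - 1)) / |markers|. A genome is
    near-complete when at least ``near_complete_min`` of a 44-marker set is
    present (scaled proportionally for other set sizes).
    """
    lut = {g.lower(): g for g in markers.genes}
    counts = {g: 0 for g in markers.genes}
    unknown = []
    for gene, c in gene_copies.items():
        if c < 0:
            raise QCError(f"negative copy count for {gene!r}")
        key = gene.lower()
        if key in lut:
            counts[lut[key]] += int(c)
        else:
            unknown.append(gene)
    present = sum(1 for c in counts.values() if c >= 1)
    extra = sum(max(0, c - 1) for c in counts.values())
    completeness = 100.0 * present / markers.size
    redundancy = 100.0 * extra / markers.size
    threshold = near_complete_min * markers.size / 44.0
    return QCReport(genome, completeness, redundancy,
                    present >= threshold, counts, sorted(unknown))


def contamination_screen(gene_names, screen: MarkerSet) -> list[str]:
    """Genes in ``gene_names`` matching the screen set (case-insensitive)."""
    wanted = {g.lower() for g in screen.genes}
    return sorted({g for g in gene_names if g.lower() in wanted})


# ---------------------------------------------------------------------------
# Dereplication

@dataclass(frozen=True)
class AniRecord:
    genomeA: str
    genomeB: str
    ani: float                        # percent
    aligned_fraction_of_smaller: float  # percent
    no_overlap: bool = False

    def canonical(self) -> "AniRecord":
        if self.genomeA <= self.genomeB:
            return self
        return AniRecord(self.genomeB, self.genomeA, self.ani,
                         self.aligned_fraction_of_smaller, self.no_overlap)


@dataclass
class DereplicationResult:
    clusters: list[list[str]]
    representatives: dict[str, str]   # genome -> representative id

    @property
    def representative_ids(self) -> list[str]:
        return sorted(set(self.representatives.values()))


def dereplicate(records: list[AniRecord], genomes: dict[str, dict],
                ani_threshold: float = 98.0,
                min_align: float = 25.0) -> DereplicationResult:
    """Single-linkage clustering of genomes redundant by ANI.

    An edge joins two genomes when ANI > ``ani_threshold`` percent AND the
    aligned fraction of the smaller genome > ``min_align`` percent. Within a
    cluster the representative is a reference genome if any (the longest
    reference when several), otherwise the longest genome; ties by id order.

    ``genomes`` maps id -> {"is_reference": bool, "length": int}.
    """
    if not (0 < ani_threshold <= 100 and 0 < min_align <= 100):
        raise QCError("thresholds must be in (0, 100]")
    parent = {g: g for g in genomes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for rec in records:
        for g in (rec.genomeA, rec.genomeB):
            if g not in genomes:
                raise QCError(f"unknown genome id {g!r} in ANI records")
        if rec.ani > ani_threshold and rec.aligned_fraction_of_smaller > min_align:
            ra, rb = find(rec.genomeA), find(rec.genomeB)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for g in genomes:
        groups.setdefault(find(g), []).append(g)
    clusters, reps = [], {}
    for members in groups.values():
        members = sorted(members)
        refs = [m for m in members if genomes[m].get("is_reference")]
        pool = refs if refs else members
        rep = max(pool, key=lambda m: (genomes[m].get("length", 0), ),
                  default=None)
        # ties by id order: max on (length,) keeps the first max; enforce
        best_len = max(genomes[m].get("length", 0) for m in pool)
        rep = min(m for m in pool if genomes[m].get("length", 0) == best_len)
        clusters.append(members)
        for m in members:
            reps[m] = rep
    clusters.sort(key=lambda c: c[0])
    return DereplicationResult(clusters, reps)


# ---------------------------------------------------------------------------
# k-mer sketch ANI

def _canonical_kmers(seq: str, k: int) -> set[int]:
    comp = str.maketrans("ACGT", "TGCA")
    seq = seq.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        rc = kmer.translate(comp)[::-1]
        out.add(hash(min(kmer, rc)))
    return out


def kmer_ani(seqA: str, seqB: str, k: int = 21) -> AniRecord:
    """Approximate ANI from the Jaccard similarity of canonical k-mer sets.

    Uses the Mash distance D = -(1/k) ln(2J / (1+J)); ANI = 100 (1 - D),
    clipped to [0, 100]. The aligned fraction of the smaller sequence is
    approximated by its fraction of shared k-mers.
    """
    if min(len(seqA), len(seqB)) < k:
        raise QCError(f"sequences must be at least k={k} long")
    ka, kb = _canonical_kmers(seqA, k), _canonical_kmers(seqB, k)
    inter = len(ka & kb)
    union = len(ka | kb)
    j = inter / union if union else 0.0
    smaller = ka if len(seqA) <= len(seqB) else kb
    frac = 100.0 * (len(smaller & (ka & kb)) / len(smaller)) if smaller else 0.0
    if j == 0.0:
        return AniRecord("A", "B", 0.0, 0.0, no_overlap=True).canonical()
    d = -(1.0 / k) * np.log(2.0 * j / (1.0 + j))
    ani = float(np.clip(100.0 * (1.0 - d), 0.0, 100.0))
    return AniRecord("A", "B", ani, frac)


# ---------------------------------------------------------------------------
# Coverage rules and linking

def apply_detection_rule(coverage: pd.DataFrame,
                         detection: pd.DataFrame,
                         cutoff: float = DETECTION_CUTOFF) -> pd.DataFrame:
    """Zero mean coverage wherever detection <= ``cutoff`` (strict '>25%').

    Both frames are genome x sample; detection values are fractions in [0, 1].
    Idempotent by construction.
    """
    if coverage.shape != detection.shape:
        raise QCError("coverage and detection tables must share shape")
    det = detection.to_numpy(float)
    if det.min() < 0 or det.max() > 1:
        raise QCError("detection must be a fraction in [0, 1]")
    return coverage.where(det > cutoff, 0.0).astype(float)


@dataclass
class LinkResult:
    pair: tuple[str, str]
    n: int
    slope: float
    intercept: float
    r: float
    r2: float
    t: float
    p: float
    detection_rule: bool | None = None


def link_organelles(covA, covB, labels: tuple[str, str] = ("A", "B"),
                    detection_rule: bool | None = None) -> LinkResult:
    """OLS regression covB ~ covA with a two-sided t test of the slope.

    R^2 is the squared Pearson correlation; p is two-sided with n-2 df.
    """
    x = np.asarray(covA, float)
    y = np.asarray(covB, float)
    if x.shape != y.shape or x.ndim != 1:
        raise QCError("coverage vectors must be equal-length 1-D")
    if len(x) < 3:
        raise QCError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise QCError("degenerate coverage vector (zero variance)")
    res = stats.linregress(x, y)
    n = len(x)
    se = res.stderr
    t = res.slope / se if se > 0 else np.inf
    return LinkResult(labels, n, float(res.slope), float(res.intercept),
                      float(res.rvalue), float(res.rvalue ** 2),
                      float(t), float(res.pvalue), detection_rule)


def rank_link_candidates(coverage: pd.DataFrame, detection: pd.DataFrame,
                         target: str,
                         candidates: list[str] | None = None,
                         ) -> pd.DataFrame:
    """Rank candidate genomes by coverage correlation with ``target``.

    Every candidate is scored both with and without the detection rule; the
    ranking key is the R^2 of the rule-off variant (the reported choice),
    descending. Returns a tidy frame with both variants per candidate.
    """
    if target not in coverage.index:
        raise QCError(f"target {target!r} not in coverage table")
    if candidates is None:
        candidates = [g for g in coverage.index if g != target]
    if not candidates:
        raise QCError("no candidates")
    ruled = apply_detection_rule(coverage, detection)
    rows = []
    for cand in candidates:
        for rule, table in ((False, coverage), (True, ruled)):
            res = link_organelles(table.loc[target], table.loc[cand],
                                  (target, cand), detection_rule=rule)
            rows.append({"candidate": cand, "detection_rule": rule,
                         "n": res.n, "slope": res.slope, "r": res.r,
                         "R2": res.r2, "t": res.t, "p": res.p})
    df = pd.DataFrame(rows)
    key = (df[~df.detection_rule].set_index("candidate").R2
           .rank(ascending=False, method="first"))
    df["rank"] = df.candidate.map(key).astype(int)
    return df.sort_values(["rank", "detection_rule"]).reset_index(drop=True)
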