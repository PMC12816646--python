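"""Multiple-sequence-alignment data model and compositional treatments.

Provides FASTA I/O, residue counting, SR4 recoding of amino acids into four
composition-robust classes, gap-threshold column trimming, Stuart's test of
marginal homogeneity between pairs of sequences, and a greedy stationarity
trimmer that removes the alignment columns driving non-stationary composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import chi2

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"

#: ambiguity / non-standard codes treated as missing data throughout
AMBIGUOUS = set("BZXJUO?.*")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate taxa, ...)."""


@dataclass
class Alignment:
    """Taxa x sites character matrix over a declared alphabet.

    Parameters
    ----------
    taxa : list of str
        Unique sequence labels, in order.
    matrix : numpy.ndarray of shape (n_taxa, n_sites), dtype '<U1'
        Characters, uppercase. Gaps are ``'-'``; ambiguity codes are kept
        verbatim but treated as missing by all analyses.
    alphabet : str
        The declared state alphabet (20 amino acids by default, or the
        class symbols of a recoded alignment).
    """

    taxa: list[str]
    matrix: np.ndarray
    alphabet: str = AMINO_ACIDS
    gap: str = GAP

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} labels for {self.matrix.shape[0]} rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dups = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dups}")
        allowed = set(self.alphabet) | {self.gap} | AMBIGUOUS
        bad = set(self.matrix.ravel()) - allowed
        if bad:
            raise AlignmentError(f"characters outside alphabet: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def take_sites(self, indices: Sequence[int]) -> "Alignment":
        return Alignment(list(self.taxa), self.matrix[:, list(indices)],
                         self.alphabet, self.gap)

    def sequences(self) -> dict[str, str]:
        return {t: "".join(r) for t, r in zip(self.taxa, self.matrix)}

    @classmethod
    def from_sequences(cls, seqs: dict[str, str] | Iterable[tuple[str, str]],
                       alphabet: str = AMINO_ACIDS) -> "Alignment":
        items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
        if not items:
            raise AlignmentError("no sequences")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        mat = np.array([list(s.upper()) for _, s in items], dtype="<U1")
        return cls([t for t, _ in items], mat, alphabet)


@dataclass(frozen=True)
class RecodingScheme:
    """A partition of the source alphabet into reduced classes."""

    name: str
    classes: dict[str, str]  # residue -> class symbol

    def class_alphabet(self) -> str:
        seen: list[str] = []
        for sym in self.classes.values():
            if sym not in seen:
                seen.append(sym)
        return "".join(seen)


#: SR4: {AGNPST} {CHWY} {DEKQR} {FILMV}, rendered as class symbols '1'-'4'
SR4 = RecodingScheme(
    "SR4",
    {**{r: "1" for r in "AGNPST"},
     **{r: "2" for r in "CHWY"},
     **{r: "3" for r in "DEKQR"},
     **{r: "4" for r in "FILMV"}},
)


def read_fasta(path, alphabet: str = AMINO_ACIDS) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are uppercased; all records must have equal length. Pass the
    class symbols as ``alphabet`` when reading a recoded alignment.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        dups = sorted({x for x in labels if labels.count(x) > 1})
        raise AlignmentError(f"duplicate taxon labels: {dups}")
    return Alignment.from_sequences([(r.id, str(r.seq)) for r in records],
                                    alphabet=alphabet)


def write_fasta(aln: Alignment, path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=t, description="")
               for t, s in aln.sequences().items()]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def recode(aln: Alignment, scheme: RecodingScheme = SR4) -> Alignment:
    """Map every residue through a recoding scheme; gaps/ambiguities pass as gaps."""
    out = np.full_like(aln.matrix, aln.gap)
    covered = np.zeros(aln.matrix.shape, dtype=bool)
    missing = (aln.matrix == aln.gap) | np.isin(aln.matrix, sorted(AMBIGUOUS))
    covered |= missing
    for residue, sym in scheme.classes.items():
        hit = aln.matrix == residue
        out[hit] = sym
        covered |= hit
    if not covered.all():
        t, s = np.argwhere(~covered)[0]
        raise AlignmentError(
            f"residue {aln.matrix[t, s]!r} at taxon {aln.taxa[t]!r}, "
            f"site {s} not covered by scheme {scheme.name}"
        )
    return Alignment(list(aln.taxa), out, scheme.class_alphabet(), aln.gap)


def residue_counts(aln: Alignment) -> np.ndarray:
    """Count residues per taxon; gaps and ambiguity codes excluded.

    Returns an integer array of shape (n_taxa, len(alphabet)) in alphabet order.
    """
    counts = np.zeros((aln.n_taxa, len(aln.alphabet)), dtype=int)
    for j, a in enumerate(aln.alphabet):
        counts[:, j] = (aln.matrix == a).sum(axis=1)
    return counts


@dataclass
class TrimResult:
    kept: list[int]
    removed: list[int]
    alignment: Alignment
    log: list[dict] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        round_of = {rec["site"]: rec["round"] for rec in self.log}
        with open(path, "w") as fh:
            fh.write("site_index\taction\tround\n")
            for i in sorted(self.kept + self.removed):
                act = "removed" if i in set(self.removed) else "kept"
                fh.write(f"{i}\t{act}\t{round_of.get(i, '')}\n")


def gap_trim(aln: Alignment, gap_threshold: float = 0.8) -> TrimResult:
    """Keep columns whose fraction of non-gap characters >= ``gap_threshold``."""
    if not 0.0 <= gap_threshold <= 1.0:
        raise ValueError("gap_threshold must be in [0, 1]")
    missing = (aln.matrix == aln.gap) | np.isin(aln.matrix, sorted(AMBIGUOUS))
    nongap_frac = 1.0 - missing.mean(axis=0)
    kept = [i for i in range(aln.n_sites) if nongap_frac[i] >= gap_threshold]
    removed = [i for i in range(aln.n_sites) if nongap_frac[i] < gap_threshold]
    return TrimResult(kept, removed, aln.take_sites(kept),
                      [{"site": i, "round": 0} for i in removed])


@dataclass
class StuartResult:
    """Stuart's test of marginal homogeneity for one pair of sequences.

    ``table`` holds the k x k co-occurrence counts N_uv over sites where both
    sequences carry an unambiguous state; ``W = d' V^- d`` is chi-squared with
    ``df`` degrees of freedom under marginal homogeneity.
    """

    pair: tuple[str, str]
    table: np.ndarray
    d: np.ndarray
    V: np.ndarray
    W: float
    df: int
    p: float
    singular: bool = False


def _stuart_from_table(table: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int, float, bool]:
    k = table.shape[0]
    rows = table.sum(axis=1).astype(float)
    cols = table.sum(axis=0).astype(float)
    d = (rows - cols)[: k - 1]
    V = np.zeros((k - 1, k - 1))
    for u in range(k - 1):
        V[u, u] = rows[u] + cols[u] - 2.0 * table[u, u]
        for v in range(u + 1, k - 1):
            V[u, v] = V[v, u] = -(table[u, v] + table[v, u])
    singular = False
    try:
        sol = np.linalg.solve(V, d)
        # guard against solve "succeeding" on an ill-conditioned matrix
        if not np.allclose(V @ sol, d, atol=1e-8 * max(1.0, np.abs(d).max())):
            raise np.linalg.LinAlgError
        W = float(d @ sol)
        df = k - 1
    except np.linalg.LinAlgError:
        singular = True
        W = float(d @ np.linalg.pinv(V, rcond=1e-10) @ d)
        df = int(np.linalg.matrix_rank(V, tol=1e-10 * max(1.0, np.abs(V).max())))
    W = max(W, 0.0)
    p = float(chi2.sf(W, df)) if df > 0 else 1.0
    return d, V, W, df, p, singular


def stuart_pair_table(aln: Alignment, taxonA: str, taxonB: str) -> np.ndarray:
    """k x k counts of co-occurring unambiguous states for a taxon pair."""
    a, b = aln.row(taxonA), aln.row(taxonB)
    idx = {c: i for i, c in enumerate(aln.alphabet)}
    k = len(aln.alphabet)
    table = np.zeros((k, k), dtype=int)
    for x, y in zip(a, b):
        if x in idx and y in idx:
            table[idx[x], idx[y]] += 1
    return table


def stuart_test(aln: Alignment, taxonA: str, taxonB: str) -> StuartResult:
    """Stuart's chi-squared test of marginal homogeneity for one sequence pair."""
    table = stuart_pair_table(aln, taxonA, taxonB)
    if table.sum() == 0:
        raise AlignmentError(
            f"no co-ungapped sites between {taxonA!r} and {taxonB!r}"
        )
    d, V, W, df, p, singular = _stuart_from_table(table)
    return StuartResult((taxonA, taxonB), table, d, V, W, df, p, singular)


def _pair_tables(aln: Alignment) -> dict[tuple[int, int], np.ndarray]:
    idx = {c: i for i, c in enumerate(aln.alphabet)}
    k = len(aln.alphabet)
    coded = np.full(aln.matrix.shape, -1, dtype=int)
    for c, i in idx.items():
        coded[aln.matrix == c] = i
    tables = {}
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            ok = (coded[i] >= 0) & (coded[j] >= 0)
            t = np.zeros((k, k), dtype=int)
            np.add.at(t, (coded[i, ok], coded[j, ok]), 1)
            tables[(i, j)] = t
    return tables, coded


def stationary_trim(aln: Alignment, alpha: float = 0.05,
                    max_removed_fraction: float = 0.5) -> TrimResult:
    """Greedy column removal until no sequence pair fails Stuart's test.

    Each round removes the single column whose deletion maximally reduces the
    summed Stuart W over the currently significant pairs (ties broken by the
    lowest original column index), then recomputes all pairwise tests. Stops
    when no pair has p < ``alpha`` or the removed fraction would exceed
    ``max_removed_fraction``.
    """
    if aln.n_taxa < 3:
        raise AlignmentError("stationary trimming needs at least 3 taxa")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n_sites = aln.n_sites
    max_remove = int(np.floor(max_removed_fraction * n_sites))
    tables, coded = _pair_tables(aln)
    kept = list(range(n_sites))
    removed: list[int] = []
    log: list[dict] = []
    rnd = 0
    while len(removed) < max_remove:
        rnd += 1
        stats = {pair: _stuart_from_table(t) for pair, t in tables.items()}
        sig = [pair for pair, s in stats.items() if s[4] < alpha]
        if not sig:
            break
        base = sum(stats[pair][2] for pair in sig)
        best_col, best_sum = None, np.inf
        for col in kept:
            total = 0.0
            for (i, j) in sig:
                u, v = coded[i, col], coded[j, col]
                t = tables[(i, j)]
                if u >= 0 and v >= 0:
                    t[u, v] -= 1
                    total += _stuart_from_table(t)[2]
                    t[u, v] += 1
                else:
                    total += stats[(i, j)][2]
                if total >= best_sum:
                    break
            if total < best_sum:
                best_sum, best_col = total, col
        if best_col is None:
            break
        kept.remove(best_col)
        removed.append(best_col)
        for (i, j), t in tables.items():
            u, v = coded[i, best_col], coded[j, best_col]
            if u >= 0 and v >= 0:
                t[u, v] -= 1
        log.append({"site": best_col, "round": rnd,
                    "W_sum_before": base, "W_sum_after": best_sum,
                    "n_significant_pairs": len(sig)})
    removed_sorted = sorted(removed)
    return TrimResult(kept, removed_sorted, aln.take_sites(kept), log)
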