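"""Iterative map-and-assemble pan-genome construction.

Accessions are processed in input order.  For each one, reads are mapped to
the current assembly with an internal k-mer seed-and-extend mapper
(substitutions only); unmapped reads are assembled with a greedy
maximal-exact-overlap assembler; contigs longer than the minimum length are
appended with provenance.  After the loop, contigs homologous to an
organelle-like decoy set are removed, and novel contigs covered >90% at >90%
identity by another retained sequence are removed as redundant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .pansim import ReadSet
from .seqio import revcomp

DEFAULT_K = 31
DEFAULT_MAX_MISMATCH = 4
DEFAULT_INSERT_RANGE = (0, 1000)


@dataclass(frozen=True)
class AlignmentRecord:
    """A single-end placement of a read; start is 0-based half-open."""

    read_id: str
    contig: str | None
    start: int
    strand: str
    mismatches: int
    mapped: bool
    length: int


@dataclass
class Contig:
    id: str
    sequence: str
    provenance: str = "reference"

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PanAssembly:
    contigs: list[Contig] = field(default_factory=list)
    added_bp: list[int] = field(default_factory=list)
    filter_log: list[dict] = field(default_factory=list)

    @classmethod
    def from_reference(cls, reference: dict[str, str]) -> "PanAssembly":
        return cls(contigs=[Contig(name, seq, "reference") for name, seq in reference.items()])

    def as_dict(self) -> dict[str, str]:
        return {c.id: c.sequence for c in self.contigs}

    @property
    def total_bp(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def novel_contigs(self) -> list[Contig]:
        return [c for c in self.contigs if c.provenance != "reference"]


# ---------------------------------------------------------------------------
# k-mer index + mapper

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes along the last axis (k <= 31 fits int64)."""
    m = mat.astype(np.int64)
    n = m.shape[-1] - k + 1
    km = np.zeros(m.shape[:-1] + (n,), dtype=np.int64)
    for j in range(k):
        km = (km << 2) | m[..., j : j + n]
    return km


class KmerIndex:
    """Exact k-mer index over a concatenated assembly (sentinel-separated)."""

    def __init__(self, assembly: PanAssembly, k: int = DEFAULT_K):
        self.k = k
        self.names = [c.id for c in assembly.contigs]
        parts, starts, pos = [], [], 0
        for c in assembly.contigs:
            starts.append(pos)
            parts.append(_encode(c.sequence))
            parts.append(np.array([4], dtype=np.uint8))
            pos += c.length + 1
        self.genome = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = self.starts + np.asarray([c.length for c in assembly.contigs], dtype=np.int64)
        if self.genome.size >= k:
            km = _kmer_codes(self.genome[None, :], k)[0]
            bad = np.concatenate([[0], np.cumsum(self.genome == 4)])
            valid = (bad[k:] - bad[:-k]) == 0
            idx = np.flatnonzero(valid)
            order = np.argsort(km[idx], kind="stable")
            # int64 codes (k <= 31 keeps them under 2^62) so scalar
            # searchsorted never up-casts the whole array
            self.sorted_codes = km[idx][order]
            self.sorted_pos = idx[order]
        else:
            self.sorted_codes = np.empty(0, dtype=np.int64)
            self.sorted_pos = np.empty(0, dtype=np.int64)

    def lookup(self, code: int, cap: int = 50) -> np.ndarray:
        lo = int(np.searchsorted(self.sorted_codes, np.int64(code), side="left"))
        hi = int(np.searchsorted(self.sorted_codes, np.int64(code), side="right"))
        return self.sorted_pos[lo : min(hi, lo + cap)]

    def lookup_ranges(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (lo, hi) index ranges for an array of k-mer codes."""
        return (
            np.searchsorted(self.sorted_codes, codes, side="left"),
            np.searchsorted(self.sorted_codes, codes, side="right"),
        )

    def contig_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.starts, gpos, side="right") - 1)

    def best_hit(self, fwd: np.ndarray, rev: np.ndarray, seed_offsets: list[int],
                 ranges_fwd: list[tuple[int, int]], ranges_rev: list[tuple[int, int]],
                 max_mismatch: int, cap: int = 50):
        """Best substitution-only placement of a read, or None.

        ``ranges_*`` hold precomputed (lo, hi) slices into the sorted k-mer
        index, one per seed offset and strand.
        """
        L = fwd.size
        best = None
        for strand, codes, ranges in (("+", fwd, ranges_fwd), ("-", rev, ranges_rev)):
            seen = set()
            for off, (lo, hi) in zip(seed_offsets, ranges):
                for p in self.sorted_pos[lo : min(hi, lo + cap)]:
                    s = int(p) - off
                    if s < 0 or s in seen:
                        continue
                    seen.add(s)
                    ci = self.contig_of(s)
                    if s + L > self.ends[ci]:
                        continue
                    mm = int(np.count_nonzero(self.genome[s : s + L] != codes))
                    if mm <= max_mismatch and (best is None or mm < best[0]):
                        best = (mm, s, strand, ci)
                        if mm == 0:
                            return best
        return best

    def scan_window(self, codes: np.ndarray, ci: int, lo: int, hi: int, max_mismatch: int):
        """Brute-force scan of one contig window for a placement (pair rescue)."""
        L = codes.size
        lo = max(lo, int(self.starts[ci]))
        hi = min(hi, int(self.ends[ci]) - L)
        if hi < lo:
            return None
        win = self.genome[lo : hi + L]
        n = hi - lo + 1
        mm = np.zeros(n, dtype=np.int32)
        for j in range(L):
            mm += win[j : j + n] != codes[j]
        i = int(np.argmin(mm))
        if mm[i] <= max_mismatch:
            return int(mm[i]), lo + i
        return None


def map_reads(
    reads: ReadSet,
    assembly: PanAssembly,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    k: int = DEFAULT_K,
    insert_range: tuple[int, int] = DEFAULT_INSERT_RANGE,
    pair_rescue: bool = True,
    index: KmerIndex | None = None,
) -> tuple[list[AlignmentRecord], list[tuple[str, str]]]:
    """Partition each mate into mapped alignments and unmapped reads.

    A mate maps iff a seed-and-extend hit with <= max_mismatch substitutions
    exists.  When exactly one mate of a pair maps, the insert window
    [pos - insert_max, pos + insert_max] on the same contig is scanned for
    the other mate (pair rescue).  Every mate appears exactly once in the
    union of the two return values.  A prebuilt :class:`KmerIndex` over the
    same assembly may be passed to amortise index construction across
    accessions.
    """
    if not assembly.contigs:
        raise ValueError("assembly is empty")
    if index is None or index.k != k:
        index = KmerIndex(assembly, k=k)
    alignments: list[AlignmentRecord] = []
    unmapped: list[tuple[str, str]] = []
    if not reads.pairs:
        return alignments, unmapped

    seqs: list[str] = []
    for _, s1, s2 in reads.pairs:
        seqs.append(s1)
        seqs.append(s2)
    lengths = {len(s) for s in seqs}
    imax = insert_range[1]

    # batch-compute seed codes per read length class
    seed_cache: dict[int, tuple] = {}
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    fwd_codes: dict[int, np.ndarray] = {}
    rev_codes: dict[int, np.ndarray] = {}
    seed_info: dict[int, tuple] = {}
    for L, idxs in by_len.items():
        mat = np.stack([_encode(seqs[i]) for i in idxs])
        rmat = 3 - mat[:, ::-1]
        if L < k:
            seed_info[L] = ([], None, None, None, None)
        else:
            km_f = _kmer_codes(mat, k)
            km_r = _kmer_codes(rmat, k)
            offsets = sorted({0, (L - k) // 2, L - k})
            lo_f, hi_f = index.lookup_ranges(km_f[:, offsets])
            lo_r, hi_r = index.lookup_ranges(km_r[:, offsets])
            seed_info[L] = (offsets, np.stack([lo_f, hi_f], -1), np.stack([lo_r, hi_r], -1), None, None)
        fwd_codes[L] = mat
        rev_codes[L] = rmat

    hits: list[tuple | None] = [None] * len(seqs)
    row_of: dict[int, int] = {}
    for L, idxs in by_len.items():
        for r, i in enumerate(idxs):
            row_of[i] = r
    short_warned = False
    for i, s in enumerate(seqs):
        L = len(s)
        offsets, rng_f, rng_r = seed_info[L][:3]
        if not offsets:
            if not short_warned:
                warnings.warn(f"reads shorter than k={k} treated as unmapped")
                short_warned = True
            continue
        r = row_of[i]
        hits[i] = index.best_hit(
            fwd_codes[L][r], rev_codes[L][r], offsets,
            rng_f[r].tolist(), rng_r[r].tolist(), max_mismatch,
        )

    if pair_rescue:
        for p in range(len(reads.pairs)):
            i1, i2 = 2 * p, 2 * p + 1
            for ia, ib in ((i1, i2), (i2, i1)):
                if hits[ia] is not None and hits[ib] is None and len(seqs[ib]) >= k:
                    _, s, _, ci = hits[ia]
                    Lb = len(seqs[ib])
                    rb = row_of[ib]
                    found = None
                    for codes, strand in ((fwd_codes[Lb][rb], "+"), (rev_codes[Lb][rb], "-")):
                        res = index.scan_window(codes, ci, s - imax, s + imax, max_mismatch)
                        if res is not None and (found is None or res[0] < found[0]):
                            found = (res[0], res[1], strand, ci)
                    if found is not None:
                        hits[ib] = found

    for p, (rid, s1, s2) in enumerate(reads.pairs):
        for mate, seq, i in ((1, s1, 2 * p), (2, s2, 2 * p + 1)):
            mid = f"{rid}/{mate}"
            h = hits[i]
            if h is None:
                unmapped.append((mid, seq))
            else:
                mm, s, strand, ci = h
                alignments.append(
                    AlignmentRecord(
                        read_id=mid,
                        contig=index.names[ci],
                        start=int(s - index.starts[ci]),
                        strand=strand,
                        mismatches=mm,
                        mapped=True,
                        length=len(seq),
                    )
                )
    return alignments, unmapped


# ---------------------------------------------------------------------------
# greedy overlap assembler


def assemble_unmapped(
    reads: list[str] | list[tuple[str, str]],
    min_contig_len: int = 500,
    min_overlap: int = DEFAULT_K,
) -> list[str]:
    """Greedy maximal-exact-overlap assembly of unmapped reads.

    Deterministic: seeds are processed in sorted order and extensions pick
    the longest exact suffix-prefix overlap extension (ties broken by read
    order).  Only contigs strictly longer than ``min_contig_len`` are
    returned.
    """
    seqs = sorted({r[1] if isinstance(r, tuple) else r for r in reads})
    seqs = [s for s in seqs if len(s) >= min_overlap]
    if not seqs:
        return []
    k = min_overlap
    index: dict[str, list[tuple[int, int, int]]] = {}
    for ri, s in enumerate(seqs):
        for strand, oriented in ((0, s), (1, revcomp(s))):
            for off in range(len(oriented) - k + 1):
                index.setdefault(oriented[off : off + k], []).append((ri, off, strand))

    used = [False] * len(seqs)

    def extend_right(contig: str) -> str:
        while True:
            key = contig[-k:]
            best = None  # (extension, ri, oriented)
            for ri, off, strand in index.get(key, ()):  # noqa: B905
                if used[ri]:
                    continue
                oriented = seqs[ri] if strand == 0 else revcomp(seqs[ri])
                ov = off + k
                ext = len(oriented) - ov
                if ext <= 0 or ov > len(contig):
                    continue
                if contig[-ov:] != oriented[:ov]:
                    continue
                if best is None or ext > best[0]:
                    best = (ext, ri, oriented)
            if best is None:
                return contig
            ext, ri, oriented = best
            used[ri] = True
            contig += oriented[-ext:]

    contigs: list[str] = []
    for ri, s in enumerate(seqs):
        if used[ri]:
            continue
        contained = any(s in c or revcomp(s) in c for c in contigs)
        if contained:
            used[ri] = True
            continue
        used[ri] = True
        contig = extend_right(s)
        contig = revcomp(extend_right(revcomp(contig)))
        contigs.append(contig)

    return [c for c in contigs if len(c) > min_contig_len]


# ---------------------------------------------------------------------------
# iterative build


def iterate_build(
    reference: dict[str, str],
    accessions: list[ReadSet],
    min_contig_len: int = 500,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    k: int = DEFAULT_K,
) -> PanAssembly:
    """Map/assemble/append loop over accessions in input order."""
    if not accessions:
        raise ValueError("need at least one accession")
    assembly = PanAssembly.from_reference(reference)
    for it, reads in enumerate(accessions, 1):
        _, unmapped = map_reads(reads, assembly, max_mismatch=max_mismatch, k=k)
        contigs = assemble_unmapped(unmapped, min_contig_len=min_contig_len, min_overlap=k)
        added = 0
        for j, seq in enumerate(contigs):
            assembly.contigs.append(
                Contig(f"{reads.accession}_it{it}_c{j}", seq, f"{reads.accession}/iteration{it}")
            )
            added += len(seq)
        assembly.added_bp.append(added)
    return assembly


# ---------------------------------------------------------------------------
# homology filters

# scoring keeps >=85% identity alignments extending (score density > 0)
# while random-sequence extension and long gap traversal stay unprofitable
_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-2,
    open_gap_score=-4,
    extend_gap_score=-2,
)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def homology(query: str, target: str, k: int = DEFAULT_K) -> tuple[float, float]:
    """(query coverage, identity) of the best local alignment, either strand.

    Returns (0, 0) when query and target share no exact k-mer.
    """
    tk = _kmer_set(target, k)
    best_cov, best_id = 0.0, 0.0
    for q in (query, revcomp(query)):
        shared = [i for i in range(len(q) - k + 1) if q[i : i + k] in tk]
        if not shared:
            continue
        aln = _aligner.align(target, q)
        if len(aln) == 0:
            continue
        a = aln[0]
        counts = a.counts()
        columns = counts.gaps + counts.identities + counts.mismatches
        ident = counts.identities / columns if columns else 0.0
        qblocks = a.aligned[1]
        covered = sum(int(e - s) for s, e in qblocks)
        cov = covered / len(q)
        if cov * ident > best_cov * best_id:
            best_cov, best_id = cov, ident
    return best_cov, best_id


def filter_contaminants(
    assembly: PanAssembly,
    decoys: dict[str, str],
    min_cov: float = 0.9,
    min_id: float = 0.9,
    k: int = DEFAULT_K,
) -> PanAssembly:
    """Drop novel contigs homologous to an organelle-like decoy.

    Reference contigs are never removed.  A novel contig is removed when
    >= min_cov of its length aligns to a decoy at >= min_id identity.
    """
    if not decoys:
        return assembly
    kept, log = [], list(assembly.filter_log)
    for c in assembly.contigs:
        if c.provenance == "reference":
            kept.append(c)
            continue
        hit = None
        for dname, dseq in decoys.items():
            cov, ident = homology(c.sequence, dseq, k=k)
            if cov >= min_cov and ident >= min_id:
                hit = (dname, cov, ident)
                break
        if hit is None:
            kept.append(c)
        else:
            log.append(
                {"contig": c.id, "reason": "contaminant", "target": hit[0],
                 "coverage": round(hit[1], 4), "identity": round(hit[2], 4)}
            )
    return PanAssembly(contigs=kept, added_bp=list(assembly.added_bp), filter_log=log)


def remove_redundant(
    assembly: PanAssembly,
    cov_thresh: float = 0.90,
    id_thresh: float = 0.90,
    mode: str = "self",
    k: int = DEFAULT_K,
) -> PanAssembly:
    """Remove novel contigs covered >cov_thresh at >id_thresh identity.

    Novel contigs are processed by descending length (longer sequence always
    retained); each is compared against retained novel contigs and, in
    ``mode="all"``, against the reference contigs too.  Idempotent.
    """
    if mode not in ("self", "all"):
        raise ValueError("mode must be 'self' or 'all'")
    refs = [c for c in assembly.contigs if c.provenance == "reference"]
    novels = sorted(assembly.novel_contigs, key=lambda c: (-c.length, c.id))
    retained: list[Contig] = []
    log = list(assembly.filter_log)
    targets_ref = refs if mode == "all" else []
    for c in novels:
        hit = None
        for t in list(targets_ref) + retained:
            if t.id == c.id:
                continue
            cov, ident = homology(c.sequence, t.sequence, k=k)
            if cov > cov_thresh and ident > id_thresh:
                hit = (t.id, cov, ident)
                break
        if hit is None:
            retained.append(c)
        else:
            log.append(
                {"contig": c.id, "reason": "redundant", "target": hit[0],
                 "coverage": round(hit[1], 4), "identity": round(hit[2], 4)}
            )
    order = {c.id: i for i, c in enumerate(assembly.contigs)}
    kept = refs + sorted(retained, key=lambda c: order[c.id])
    return PanAssembly(contigs=kept, added_bp=list(assembly.added_bp), filter_log=log)


def build_pangenome(
    reference: dict[str, str],
    accessions: list[ReadSet],
    decoys: dict[str, str] | None = None,
    min_contig_len: int = 500,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    redundancy_mode: str = "self",
) -> PanAssembly:
    """Full build: iterate, screen contaminants, remove redundancy."""
    assembly = iterate_build(reference, accessions, min_contig_len=min_contig_len, max_mismatch=max_mismatch)
    if decoys:
        assembly = filter_contaminants(assembly, decoys)
    return remove_redundant(assembly, mode=redundancy_mode)
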