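"""Competitive dual-genome read assignment and exon reconciliation.

Allele-specific expression in F1 hybrids requires assigning each RNA-seq read
to the parental species it derives from.  The approach here is deliberately
strict: a read is assigned to a species only if it matches a genome of that
species *exactly* (zero mismatches) at *exactly one* location, while having no
exact match anywhere in the other species' genomes.  Reads matching both
species are ambiguous and discarded, reads with several matches within their
own species are discarded as multi-mappers, and reads matching nowhere are
unmapped.  Because the criterion is exact matching, a substring index gives
identical results to a heuristic aligner and is used instead.

Counting is restricted to exon sequence that is present in every transcript of
a gene ("constitutive") and alignable between the two species ("conserved").
Coordinates are converted between genomes with UCSC chain files; a minimal
chain parser and liftover are implemented here (positions inside aligned
blocks map affinely, positions in gaps do not lift).

Coordinates are 0-based half-open internally; GFF3 is 1-based closed at the
I/O boundary; chain files follow the UCSC spec.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("cistrans")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: parental mismap-rate threshold above which a gene is filtered
MISMAP_THRESHOLD = 0.01
#: CPM filter defaults: gene removed if CPM <= CPM_MAX in >= min_libraries
CPM_MAX = 3.0
MIN_LIBRARIES = {"hemocyte": 3, "fat_body": 5}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# UCSC chain files and liftover
# ---------------------------------------------------------------------------

class ChainParseError(ValueError):
    pass


@dataclass
class Chain:
    """A single-chromosome alignment chain (target = genome A, query = B).

    ``blocks`` is an (n, 4) integer array of ``[t_start, t_end, q_start,
    q_end]`` rows; blocks are gapless, equal-length on both genomes,
    non-overlapping and strictly increasing on both coordinate systems.
    """

    t_name: str
    t_size: int
    q_name: str
    q_size: int
    blocks: np.ndarray

    def __post_init__(self) -> None:
        self.blocks = np.asarray(self.blocks, dtype=np.int64).reshape(-1, 4)
        b = self.blocks
        if b.size:
            if ((b[:, 1] - b[:, 0]) != (b[:, 3] - b[:, 2])).any():
                raise ChainParseError("chain blocks must be equal length on both genomes")
            if (np.diff(b[:, 0]) <= 0).any() or (np.diff(b[:, 2]) <= 0).any():
                raise ChainParseError("chain blocks must be strictly increasing")
            if (b[1:, 0] < b[:-1, 1]).any() or (b[1:, 2] < b[:-1, 3]).any():
                raise ChainParseError("chain blocks must not overlap")

    def invert(self) -> "Chain":
        blocks = self.blocks[:, [2, 3, 0, 1]]
        return Chain(self.q_name, self.q_size, self.t_name, self.t_size, blocks)


def read_chain(path) -> Chain:
    """Parse a UCSC chain file holding one chain on + strands."""
    lines = Path(path).read_text().splitlines()
    header = None
    blocks = []
    t_pos = q_pos = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            if header is not None:
                raise ChainParseError(f"line {lineno}: multiple chains not supported")
            f = line.split()
            if len(f) != 13:
                raise ChainParseError(f"line {lineno}: malformed chain header")
            if f[4] != "+" or f[9] != "+":
                raise ChainParseError(f"line {lineno}: only + strands supported")
            header = dict(
                t_name=f[2], t_size=int(f[3]), t_start=int(f[5]),
                q_name=f[7], q_size=int(f[8]), q_start=int(f[10]),
            )
            t_pos, q_pos = header["t_start"], header["q_start"]
        else:
            if header is None:
                raise ChainParseError(f"line {lineno}: alignment data before chain header")
            f = line.split()
            if len(f) not in (1, 3):
                raise ChainParseError(f"line {lineno}: expected 'size [dt dq]'")
            size = int(f[0])
            blocks.append((t_pos, t_pos + size, q_pos, q_pos + size))
            if len(f) == 3:
                t_pos += size + int(f[1])
                q_pos += size + int(f[2])
    if header is None:
        raise ChainParseError("no chain header found")
    return Chain(header["t_name"], header["t_size"], header["q_name"], header["q_size"],
                 np.array(blocks))


def write_chain(chain: Chain, path) -> None:
    b = chain.blocks
    with open(path, "w") as fh:
        fh.write(
            f"chain 1000 {chain.t_name} {chain.t_size} + {b[0, 0]} {b[-1, 1]} "
            f"{chain.q_name} {chain.q_size} + {b[0, 2]} {b[-1, 3]} 1\n"
        )
        for i in range(len(b)):
            size = b[i, 1] - b[i, 0]
            if i < len(b) - 1:
                dt = b[i + 1, 0] - b[i, 1]
                dq = b[i + 1, 2] - b[i, 3]
                fh.write(f"{size} {dt} {dq}\n")
            else:
                fh.write(f"{size}\n")
        fh.write("\n")


def liftover(position: int, chain: Chain, direction: str = "a_to_b") -> int | None:
    """Map a 0-based position through the chain; ``None`` inside a gap.

    ``direction`` is ``"a_to_b"`` (target to query) or ``"b_to_a"``.
    """
    b = chain.blocks
    if direction == "a_to_b":
        starts, ends, partner = b[:, 0], b[:, 1], b[:, 2]
    elif direction == "b_to_a":
        starts, ends, partner = b[:, 2], b[:, 3], b[:, 0]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    i = bisect_right(starts.tolist(), position) - 1
    if i < 0 or position >= ends[i]:
        return None
    return int(partner[i] + (position - starts[i]))


def lift_interval(start: int, end: int, chain: Chain, direction: str = "a_to_b"):
    """Lift a half-open interval; returns aligned sub-segments as
    ``(a_start, a_end, b_start, b_end)`` tuples (possibly split at gaps)."""
    b = chain.blocks if direction == "a_to_b" else chain.blocks[:, [2, 3, 0, 1]]
    out = []
    for t_s, t_e, q_s, q_e in b:
        lo, hi = max(start, t_s), min(end, t_e)
        if lo < hi:
            out.append((lo, hi, q_s + (lo - t_s), q_s + (hi - t_s)))
    return out


# ---------------------------------------------------------------------------
# GFF3 annotations and constitutive / conserved exons
# ---------------------------------------------------------------------------

def read_gff3(path) -> pd.DataFrame:
    """Read a GFF3 into an exon table (gene_id, transcript_id, start, end).

    ``start``/``end`` are 0-based half-open.  Assumes the gene -> mRNA -> exon
    parent hierarchy used throughout this package.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for tx in db.features_of_type("mRNA"):
        gene_id = tx.attributes["Parent"][0]
        for ex in db.children(tx, featuretype="exon", order_by="start"):
            rows.append((gene_id, tx.id, ex.seqid, ex.start - 1, ex.end))
    return pd.DataFrame(rows, columns=["gene_id", "transcript_id", "seqid", "start", "end"])


def write_gff3(annotation: pd.DataFrame, path, seqid: str | None = None) -> None:
    """Write an exon table (0-based half-open) as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, gdf in annotation.groupby("gene_id", sort=False):
            chrom = seqid or gdf["seqid"].iloc[0]
            g_start, g_end = gdf["start"].min() + 1, gdf["end"].max()
            fh.write(f"{chrom}\tcistrans\tgene\t{g_start}\t{g_end}\t.\t+\t.\tID={gene_id}\n")
            for tx_id, tdf in gdf.groupby("transcript_id", sort=False):
                t_start, t_end = tdf["start"].min() + 1, tdf["end"].max()
                fh.write(f"{chrom}\tcistrans\tmRNA\t{t_start}\t{t_end}\t.\t+\t.\t"
                         f"ID={tx_id};Parent={gene_id}\n")
                for i, row in enumerate(tdf.sort_values("start").itertuples(), start=1):
                    fh.write(f"{chrom}\tcistrans\texon\t{row.start + 1}\t{row.end}\t.\t+\t.\t"
                             f"ID={tx_id}.e{i};Parent={tx_id}\n")


def constitutive_exons(annotation: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Exon intervals present (with identical boundaries) in every transcript."""
    out: dict[str, list[tuple[int, int]]] = {}
    for gene_id, gdf in annotation.groupby("gene_id", sort=False):
        per_tx = [set(map(tuple, tdf[["start", "end"]].to_numpy()))
                  for _, tdf in gdf.groupby("transcript_id", sort=False)]
        shared = set.intersection(*per_tx)
        out[gene_id] = sorted(shared)
    return out


@dataclass
class ConservedExonSet:
    """Per-gene exon segments alignable between the genomes.

    ``segments[gene]`` is a list of ``(a_start, a_end, b_start, b_end)``
    tuples of identical length on both genomes; they are the intersection of
    the gene's constitutive exons in species A with the lift-over of its
    constitutive exons in species B.
    """

    segments: dict[str, list[tuple[int, int, int, int]]]
    dropped: list[str] = field(default_factory=list)

    def intervals(self, genome: str) -> dict[str, list[tuple[int, int]]]:
        lo, hi = (0, 1) if genome == "a" else (2, 3)
        return {g: [(s[lo], s[hi]) for s in segs] for g, segs in self.segments.items()}


def derive_conserved_constitutive_exons(
    annotation_a: pd.DataFrame, annotation_b: pd.DataFrame, chain: Chain
) -> ConservedExonSet:
    """Reconcile the two species' annotations into shared exon sequence.

    For each gene present in both annotations, constitutive exons of genome A
    are lifted through the chain and intersected with the constitutive exons
    of genome B; only the overlapping, alignable sequence is retained, so
    boundary changes and species-specific exons cannot masquerade as
    expression differences.  Genes absent from one annotation are dropped
    (logged, not an error).
    """
    const_a = constitutive_exons(annotation_a)
    const_b = constitutive_exons(annotation_b)
    segments: dict[str, list[tuple[int, int, int, int]]] = {}
    dropped = []
    for gene_id in const_a:
        if gene_id not in const_b:
            dropped.append(gene_id)
            logger.info("gene %s absent from annotation B; dropped", gene_id)
            continue
        b_exons = const_b[gene_id]
        segs = []
        for a_s, a_e in const_a[gene_id]:
            for seg_a_s, seg_a_e, seg_b_s, seg_b_e in lift_interval(a_s, a_e, chain):
                # intersect the lifted segment with B's constitutive exons
                for b_s, b_e in b_exons:
                    lo, hi = max(seg_b_s, b_s), min(seg_b_e, b_e)
                    if lo < hi:
                        off_lo, off_hi = lo - seg_b_s, hi - seg_b_s
                        segs.append((seg_a_s + off_lo, seg_a_s + off_hi, lo, hi))
        segments[gene_id] = sorted(segs)
    for gene_id in const_b:
        if gene_id not in const_a:
            dropped.append(gene_id)
            logger.info("gene %s absent from annotation A; dropped", gene_id)
    return ConservedExonSet(segments, dropped)


# ---------------------------------------------------------------------------
# Exact-match read assignment
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Substring index over fixed-length windows of a genome.

    Both strands are searched: a location is a (position, strand) pair, so a
    palindromic window at one position on both strands counts twice, matching
    how an aligner reports strand-resolved alignments.
    """

    def __init__(self, seq: str):
        self.seq = seq.upper()
        self._windows: dict[int, dict[str, list[int]]] = {}

    def _index(self, k: int) -> dict[str, list[int]]:
        if k not in self._windows:
            idx: dict[str, list[int]] = {}
            s = self.seq
            for i in range(len(s) - k + 1):
                idx.setdefault(s[i:i + k], []).append(i)
            self._windows[k] = idx
        return self._windows[k]

    def locations(self, read: str) -> list[tuple[int, str]]:
        read = read.upper()
        if not read:
            raise ValueError("empty read")
        if len(read) > len(self.seq):
            return []
        idx = self._index(len(read))
        locs = [(p, "+") for p in idx.get(read, [])]
        locs += [(p, "-") for p in idx.get(revcomp(read), [])]
        return locs


@dataclass
class GenomeSet:
    """The genomes reads are competitively matched against.

    ``sim`` / ``sec`` each hold one or two :class:`GenomeIndex` objects: the
    line-specific genome and optionally the published reference.  With no
    references supplied the scheme collapses to plain two-genome competition.
    """

    sim: list[GenomeIndex]
    sec: list[GenomeIndex]

    @classmethod
    def from_sequences(cls, sim_line: str, sec_line: str,
                       sim_ref: str | None = None, sec_ref: str | None = None):
        sim = [GenomeIndex(sim_line)] + ([GenomeIndex(sim_ref)] if sim_ref else [])
        sec = [GenomeIndex(sec_line)] + ([GenomeIndex(sec_ref)] if sec_ref else [])
        return cls(sim, sec)


VERDICTS = ("sim", "sec", "ambiguous", "unmapped", "multi")


def assign_read(read: str, genomes: GenomeSet, max_locations: int = 1):
    """Assign one read; returns ``(verdict, position, strand)``.

    The verdict is ``sim`` iff the read matches exactly one location in at
    least one simulans-side genome and no location in any sechellia-side
    genome (symmetrically for ``sec``); matches on both sides are
    ``ambiguous``; several locations within the own species are ``multi``;
    no match anywhere is ``unmapped``.  ``max_locations`` mirrors an
    aligner's reportable-alignment cap; with the default 1 a read is kept iff
    it has a single exact location.
    """
    sim_locs = [g.locations(read) for g in genomes.sim]
    sec_locs = [g.locations(read) for g in genomes.sec]
    sim_any = any(locs for locs in sim_locs)
    sec_any = any(locs for locs in sec_locs)
    if sim_any and sec_any:
        return "ambiguous", None, None
    if not sim_any and not sec_any:
        return "unmapped", None, None
    locs, label = (sim_locs, "sim") if sim_any else (sec_locs, "sec")
    # prefer the line genome (first) when both report a unique location
    for genome_locs in locs:
        if len(genome_locs) == 1 and len(genome_locs) <= max_locations:
            pos, strand = genome_locs[0]
            return label, pos, strand
    return "multi", None, None


def assign_reads(reads, genomes: GenomeSet) -> pd.DataFrame:
    """Assign an iterable of ``(read_id, sequence)`` pairs.

    Returns a DataFrame with columns read_id, verdict, position, strand; the
    verdicts partition the input (every read gets exactly one).
    """
    rows = []
    for read_id, seq in reads:
        verdict, pos, strand = assign_read(seq, genomes)
        rows.append((read_id, verdict, pos, strand))
    return pd.DataFrame(rows, columns=["read_id", "verdict", "position", "strand"])


# ---------------------------------------------------------------------------
# Counting reads into conserved constitutive exons
# ---------------------------------------------------------------------------

def _exon_tree(intervals: dict[str, list[tuple[int, int]]]) -> IntervalTree:
    tree = IntervalTree()
    for gene_id, ivs in intervals.items():
        for s, e in ivs:
            if s < e:
                tree[s:e] = gene_id
    return tree


def count_alleles(
    assignments: pd.DataFrame,
    exons: ConservedExonSet,
    chain: Chain,
    annotation_a: pd.DataFrame,
    annotation_b: pd.DataFrame,
    read_length: int,
) -> pd.Series:
    """Tally assigned reads into genes, HTSeq-style union overlap.

    A read increments gene g iff its mapped interval overlaps g's conserved
    constitutive exons in its own genome's coordinates AND its lifted interval
    overlaps an exon annotated in the partner genome.  Reads hitting conserved
    exons of two genes are discarded (ambiguous feature); reads whose lifted
    interval misses the partner annotation are discarded.

    ``assignments`` must carry columns verdict ('sim' reads hold genome-A
    coordinates, 'sec' reads genome-B), position.  Returns a Series indexed by
    (gene_id, allele).
    """
    tree_a = _exon_tree(exons.intervals("a"))
    tree_b = _exon_tree(exons.intervals("b"))
    const_a = _exon_tree(constitutive_exons(annotation_a))
    const_b = _exon_tree(constitutive_exons(annotation_b))
    counts: dict[tuple[str, str], int] = {}
    for row in assignments.itertuples():
        if row.verdict not in ("sim", "sec"):
            continue
        own_tree, partner_tree, direction = (
            (tree_a, const_b, "a_to_b") if row.verdict == "sim" else (tree_b, const_a, "b_to_a")
        )
        start = int(row.position)
        end = start + read_length
        genes = {iv.data for iv in own_tree[start:end]}
        if len(genes) != 1:
            continue  # no conserved exon, or ambiguous feature overlap
        lifted = lift_interval(start, end, chain, direction)
        if not any(partner_tree[ls[2]:ls[3]] for ls in lifted):
            continue  # lifted interval misses the partner annotation
        key = (genes.pop(), row.verdict)
        counts[key] = counts.get(key, 0) + 1
    idx = pd.MultiIndex.from_tuples(counts.keys(), names=["gene_id", "allele"]) if counts \
        else pd.MultiIndex.from_tuples([], names=["gene_id", "allele"])
    return pd.Series(list(counts.values()), index=idx, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# Parental mismapping filter
# ---------------------------------------------------------------------------

def estimate_mismap(
    gene_counts_by_library: pd.DataFrame,
    library_species: dict[str, str],
    threshold: float = MISMAP_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene mismapping rates from parental libraries.

    ``gene_counts_by_library`` has a (gene_id, allele) MultiIndex and one
    column per parental library; ``library_species`` maps library name to its
    true species.  The mismap rate of a gene within one parental species is
    the fraction of its assigned reads carrying the wrong-species verdict.  A
    gene is ``filtered`` if the rate exceeds ``threshold`` in either species;
    genes with no assigned reads in a species are ``untestable`` there.
    """
    genes = sorted(gene_counts_by_library.index.get_level_values("gene_id").unique())
    rows = []
    for gene in genes:
        sub = gene_counts_by_library.loc[[gene]]
        rates = {}
        for species in ("sim", "sec"):
            libs = [c for c in sub.columns if library_species[c] == species]
            total = sub[libs].to_numpy().sum()
            if total == 0:
                rates[species] = np.nan
                continue
            wrong_allele = "sec" if species == "sim" else "sim"
            wrong = sub.xs(wrong_allele, level="allele")[libs].to_numpy().sum() \
                if wrong_allele in sub.index.get_level_values("allele") else 0
            rates[species] = wrong / total
        untestable = any(np.isnan(r) for r in rates.values())
        filtered = any((not np.isnan(r)) and r > threshold for r in rates.values())
        rows.append((gene, rates["sim"], rates["sec"], filtered, untestable))
    return pd.DataFrame(
        rows, columns=["gene_id", "rate_sim", "rate_sec", "filtered", "untestable"]
    ).set_index("gene_id")


def cpm_filter(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    cpm_max: float = CPM_MAX,
    min_libraries: int = 3,
) -> pd.Series:
    """Low-expression filter: drop a gene iff its CPM is <= ``cpm_max`` in at
    least ``min_libraries`` libraries.  Returns a boolean retained mask."""
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = counts / library_sizes.reindex(counts.columns).to_numpy() * 1e6
    n_low = (cpm <= cpm_max).sum(axis=1)
    return n_low < min_libraries
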