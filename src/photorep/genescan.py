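"""Homology-based gene-model prediction on genome scaffolds.

Desk-scale stand-in for a targeted annotation pipeline: reference proteins
are searched against six-frame translations of each scaffold (seeded
Smith-Waterman with affine gaps over BLOSUM62), hits on one scaffold and
strand are clustered (genomic gap <= max_intron) and chained by dynamic
programming into collinear exon chains, splice boundaries are refined to
GT..AG dinucleotides by re-scoring the translated junction against the
reference, the open reading frame is completed to its start/stop codons,
and overlapping models from different references collapse to the best
scoring one per locus.

Internal coordinates are 0-based half-open on the *coding* strand; the
`GeneModel` surface converts to genomic (forward-strand) coordinates, and
GFF3 output is 1-based inclusive.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from ._seq import blosum62, make_local_aligner, revcomp, translate

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GenescanConfig:
    seed_length: int = 4
    two_hit_window: int = 60     # residues; a band needs 2 seeds this close
    band_tolerance: int = 8      # diagonal fuzz when grouping seeds
    band_margin: int = 20        # residues of context around a band's window
    min_align_score: float = 60.0
    max_intron: int = 20000      # nt
    splice_search: int = 60      # nt around a raw boundary to look for GT..AG
    orf_extension: int = 60      # nt to walk when completing start/stop codons
    min_chain_score: float = 100.0
    max_target_gap: int = 10     # residues; larger alignment gaps split a hit
    max_query_overlap: int = 40  # residues; chained hits may overlap this much
                                 # in the query (alignment overruns at junctions
                                 # can swallow most of a short neighboring exon)


@dataclass
class GeneModel:
    model_id: str
    scaffold_id: str
    strand: str
    exons: list                    # genomic 0-based half-open intervals, sorted
    protein: str
    query_id: str
    score: float
    has_start: bool = False
    has_stop: bool = False
    internal_stops: int = 0

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class LocalHit:
    """One seeded local alignment segment of a query against a frame."""

    query_id: str
    scaffold_id: str
    strand: str
    frame: int
    q_span: tuple                  # query residue interval, 0-based half-open
    c_span: tuple                  # coding-strand nucleotide interval
    score: float
    c_anchor: int = 0              # codon start (coding strand) of the hit's
    q_anchor: int = 0              # largest gap-free block, and its query index

    def query_index_at(self, c: int) -> int:
        """Query residue index of the codon starting at ``c`` (same phase)."""
        return self.q_anchor + (c - self.c_anchor) // 3


# ---------------------------------------------------------------------------
# six-frame translation


@dataclass
class FrameTranslation:
    scaffold_id: str
    strand: str            # '+' or '-'
    frame: int             # 0, 1, 2 offset within the (rc-)sequence
    peptide: str
    seq_len: int

    def pep_to_coding(self, p0: int, p1: int) -> tuple:
        """Peptide interval -> nucleotide interval on the coding strand."""
        return (self.frame + 3 * p0, self.frame + 3 * p1)

    def coding_to_genomic(self, c0: int, c1: int) -> tuple:
        if self.strand == "+":
            return (c0, c1)
        return (self.seq_len - c1, self.seq_len - c0)


def six_frame_translate(scaffold_id: str, seq: str) -> list:
    """Three forward and three reverse-complement frame translations."""
    out = []
    if not seq:
        return out
    rc = revcomp(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for f in range(3):
            out.append(FrameTranslation(scaffold_id, strand, f,
                                        translate(s[f:]), len(seq)))
    return out


# ---------------------------------------------------------------------------
# seeded local alignment


def _kmer_index(seq: str, k: int) -> dict:
    idx = defaultdict(list)
    for i in range(len(seq) - k + 1):
        idx[seq[i:i + k]].append(i)
    return idx


def _segment_hits(aln, query, window, w0, frame, query_id, config, matrix) -> list:
    """Split an alignment at large gaps; rescore each ungapped-ish segment."""
    qb, tb = aln.aligned  # target=query blocks, query=window blocks
    segments = []
    cur = []
    for (qs, qe), (ts, te) in zip(qb, tb):
        if cur:
            pq, pt = cur[-1]
            if (qs - pq[1]) >= config.max_target_gap or (ts - pt[1]) >= config.max_target_gap:
                segments.append(cur)
                cur = []
        cur.append(((qs, qe), (ts, te)))
    if cur:
        segments.append(cur)
    hits = []
    for seg in segments:
        score = 0.0
        for (qs, qe), (ts, te) in seg:
            for i in range(qe - qs):
                try:
                    score += matrix[query[qs + i], window[ts + i]]
                except (KeyError, IndexError):
                    score += -4.0
        # small internal gaps: charge affine penalties
        for a, b in zip(seg, seg[1:]):
            gq = b[0][0] - a[0][1]
            gt = b[1][0] - a[1][1]
            g = max(gq, gt)
            if g > 0:
                score -= 11.0 + (g - 1) * 1.0
        if score < config.min_align_score:
            continue
        q0, q1 = seg[0][0][0], seg[-1][0][1]
        t0, t1 = seg[0][1][0] + w0, seg[-1][1][1] + w0
        big = max(seg, key=lambda blk: blk[0][1] - blk[0][0])
        c_anchor = frame.pep_to_coding(big[1][0] + w0, big[1][0] + w0 + 1)[0]
        hits.append(LocalHit(query_id, frame.scaffold_id, frame.strand, frame.frame,
                             (q0, q1), frame.pep_to_coding(t0, t1), score,
                             c_anchor=c_anchor, q_anchor=big[0][0]))
    return hits


def local_align(query_id: str, query: str, frame: FrameTranslation,
                config: GenescanConfig | None = None, aligner=None,
                frame_index: dict | None = None, matrix=None) -> list:
    """Seeded Smith-Waterman of one query against one frame translation.

    Exact k-mer seed matches sharing a diagonal band (two-hit rule) trigger
    an affine-gap local alignment on the banded window; alignments are
    split at gaps larger than a typical splice offset and segments scoring
    below ``min_align_score`` are dropped.  Coordinates are on the coding
    strand.
    """
    config = config or GenescanConfig()
    aligner = aligner or make_local_aligner()
    matrix = matrix if matrix is not None else blosum62()
    pep = frame.peptide
    k = config.seed_length
    if len(query) < k or len(pep) < k:
        return []
    if frame_index is None:
        frame_index = _kmer_index(pep, k)
    seeds = []  # (tpos, diag)
    for q in range(len(query) - k + 1):
        for t in frame_index.get(query[q:q + k], ()):
            seeds.append((t, t - q))
    if not seeds:
        return []
    seeds.sort()
    # greedy banding: a seed joins an open band when it is near the band's
    # diagonal and close along the target; bands therefore never span introns
    bands = []
    open_bands = []  # [diag0, last_t, [seeds]]
    for t, diag in seeds:
        open_bands = [b for b in open_bands if t - b[1] <= 3 * config.two_hit_window]
        placed = False
        for b in open_bands:
            if abs(diag - b[0]) <= config.band_tolerance:
                b[1] = t
                b[2].append((diag, t))
                placed = True
                break
        if not placed:
            nb = [diag, t, [(diag, t)]]
            open_bands.append(nb)
            bands.append(nb[2])

    hits = []
    seen_windows = set()
    for band in bands:
        if len(band) < 2:
            continue
        positions = sorted(t for _, t in band)
        if positions[-1] - positions[0] > 3 * len(query):
            continue
        if not any(b - a <= config.two_hit_window for a, b in zip(positions, positions[1:])):
            continue
        w0 = max(0, positions[0] - config.band_margin)
        w1 = min(len(pep), positions[-1] + k + config.band_margin)
        if (w0, w1) in seen_windows:
            continue
        seen_windows.add((w0, w1))
        window = pep[w0:w1]
        alns = aligner.align(query, window)
        if len(alns) == 0 or alns.score < config.min_align_score:
            continue
        hits.extend(_segment_hits(alns[0], query, window, w0, frame, query_id,
                                  config, matrix))
    # drop hits mostly nested inside a better hit
    hits.sort(key=lambda h: -h.score)
    kept = []
    for h in hits:
        if any(_overlap(h.c_span, g.c_span) > 0.5 * (h.c_span[1] - h.c_span[0])
               for g in kept):
            continue
        kept.append(h)
    return kept


def _overlap(a: tuple, b: tuple) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


# ---------------------------------------------------------------------------
# exon chaining


def chain_hits(hits: list, max_intron: int = 20000, max_query_overlap: int = 6) -> tuple:
    """Best collinear chain (list of hits, total score) by dynamic programming.

    Hits must share scaffold/strand/query.  A chain is collinear when both
    query spans and coding coordinates increase (query spans may overlap by
    at most ``max_query_overlap`` residues, absorbing alignment overruns at
    exon junctions), with genomic gaps at most ``max_intron``.  Chain score
    is the sum of member scores.
    """
    if not hits:
        return [], 0.0
    hits = sorted(hits, key=lambda h: (h.c_span[0], h.c_span[1], h.q_span[0]))
    n = len(hits)
    best_score = [h.score for h in hits]
    back = [-1] * n
    for j in range(n):
        for i in range(j):
            a, b = hits[i], hits[j]
            if a.q_span[1] - max_query_overlap <= b.q_span[0] \
                    and a.q_span[0] < b.q_span[0] and a.c_span[1] <= b.c_span[0] \
                    and b.c_span[0] - a.c_span[1] <= max_intron:
                cand = best_score[i] + b.score
                if cand > best_score[j]:
                    best_score[j] = cand
                    back[j] = i
    j = max(range(n), key=lambda i: best_score[i])
    total = best_score[j]
    chain = []
    while j != -1:
        chain.append(hits[j])
        j = back[j]
    return list(reversed(chain)), total


# ---------------------------------------------------------------------------
# model construction


def _pair_score(matrix, x: str, y: str) -> float:
    try:
        return float(matrix[x, y])
    except (KeyError, IndexError):
        return -4.0


def _refine_junction(coding: str, query: str, left: LocalHit, right: LocalHit,
                     donor: int, acceptor: int, config: GenescanConfig,
                     matrix) -> tuple:
    """Pick the GT..AG donor/acceptor pair that best restores the reference.

    Donor candidates keep the left exon's codon phase; query continuity
    (the codon after the donor resumes at the acceptor) then determines
    the acceptor uniquely from the two hits' gap-free-block registrations,
    so only the AG dinucleotide needs checking.  Candidates are scored
    codon by codon against each hit's own query registration; alignment
    overruns into the intron lose because their chance matches cannot beat
    the real exon codons they would displace.
    """
    # widen the search by the observed query overlap between the flanking
    # hits: overlapping residues measure how far the alignments overran
    # into the intron on each side
    overlap_nt = 3 * max(0, left.q_span[1] - right.q_span[0])
    S = config.splice_search + overlap_nt
    flank_codons = 16

    def side_score(lo, hi, hit):
        s = 0.0
        for c in range(lo, hi, 3):
            qi = hit.query_index_at(c)
            if 0 <= qi < len(query):
                s += _pair_score(matrix, translate(coding[c:c + 3]), query[qi])
            else:
                s += -4.0
        return s

    best = None
    for d in range(donor - S, donor + S + 1):
        if (d - left.c_anchor) % 3 or d < 3 or d + 2 > len(coding) \
                or coding[d:d + 2] != "GT":
            continue
        # continuity: residue index after the donor equals the acceptor's
        boundary_q = left.query_index_at(d)
        a = right.c_anchor + 3 * (boundary_q - right.q_anchor)
        if a <= d + 4 or a - 2 < 0 or a + 3 > len(coding) \
                or abs(a - acceptor) > 2 * S or coding[a - 2:a] != "AG":
            continue
        sL = side_score(max(left.c_anchor % 3, d - 3 * flank_codons), d, left)
        sR = side_score(a, min(len(coding) - 2, a + 3 * flank_codons), right)
        shift = abs(d - donor) + abs(a - acceptor)
        key = (-(sL + sR), shift, d, a)
        if best is None or key < best[0]:
            best = (key, d, a)
    if best is None:
        return donor, acceptor
    return best[1], best[2]


def _complete_orf(coding: str, start: int, end: int, config: GenescanConfig) -> tuple:
    """Walk the CDS ends to the nearest in-frame start/stop codons.

    The start search looks both upstream (alignment trimmed the first
    residues) and downstream (alignment overran into flanking sequence)
    and takes the nearest in-frame ATG; the upstream walk stops at a stop
    codon.
    """
    limit = config.orf_extension
    if coding[start:start + 3] != "ATG":
        cand = None
        up_blocked = False
        for shift in range(3, limit + 3, 3):
            up = start - shift
            if not up_blocked and up >= 0:
                codon = coding[up:up + 3]
                if codon == "ATG":
                    cand = up
                    break
                if codon in _STOPS:
                    up_blocked = True
            down = start + shift
            if down + 3 <= end and coding[down:down + 3] == "ATG":
                cand = down
                break
        if cand is not None:
            start = cand
    has_start = coding[start:start + 3] == "ATG"
    moved = 0
    while end + 3 <= len(coding) and coding[end:end + 3] not in _STOPS and moved < limit:
        end += 3
        moved += 3
    has_stop = end + 3 <= len(coding) and coding[end:end + 3] in _STOPS
    if has_stop:
        end += 3  # stop codon included in the CDS
    return start, end, has_start, has_stop


def build_model(chain: list, chain_score: float, query: str, coding: str,
                seq_len: int, config: GenescanConfig, matrix,
                model_id: str) -> GeneModel | None:
    """Assemble one GeneModel from a collinear hit chain (coding-strand space)."""
    strand = chain[0].strand
    # snap every raw exon boundary to its own hit's gap-free codon phase
    exons = []
    for h in chain:
        s, e = h.c_span
        s += (h.c_anchor - s) % 3
        e -= (e - h.c_anchor) % 3
        exons.append([s, e])

    for i in range(len(exons) - 1):
        donor, acceptor = exons[i][1], exons[i + 1][0]
        if acceptor - donor < 6:
            continue
        d, a = _refine_junction(coding, query, chain[i], chain[i + 1],
                                donor, acceptor, config, matrix)
        exons[i][1], exons[i + 1][0] = d, a

    start, end, has_start, has_stop = _complete_orf(coding, exons[0][0], exons[-1][1], config)
    exons[0][0], exons[-1][1] = start, end

    cds = "".join(coding[s:e] for s, e in exons)
    protein = translate(cds)
    if protein.endswith("*"):
        protein = protein[:-1]
    # a stop codon within the final few codons means the last exon overran;
    # pull the model back to that stop (real pseudogene stops sit deeper)
    tail = protein[-12:]
    if "*" in tail:
        cut = len(protein) - len(tail) + tail.index("*")
        keep_nt = (cut + 1) * 3  # truncated protein + its stop codon
        acc = 0
        new_exons = []
        for s, e in exons:
            if acc + (e - s) >= keep_nt:
                new_exons.append([s, s + keep_nt - acc])
                break
            new_exons.append([s, e])
            acc += e - s
        exons = new_exons
        protein = protein[:cut]
        has_stop = True
        cds = "".join(coding[s:e] for s, e in exons)
    if len(cds) % 3 != 0:
        has_stop = False  # frame not restored: flag incomplete

    if strand == "+":
        gexons = [(s, e) for s, e in exons]
    else:
        gexons = sorted((seq_len - e, seq_len - s) for s, e in exons)
    return GeneModel(model_id=model_id, scaffold_id=chain[0].scaffold_id,
                     strand=strand, exons=gexons, protein=protein,
                     query_id=chain[0].query_id, score=chain_score,
                     has_start=has_start, has_stop=has_stop,
                     internal_stops=protein.count("*"))


def predict_gene_models(scaffolds: dict, panel: dict,
                        config: GenescanConfig | None = None) -> list:
    """Predict gene models on every scaffold from a reference protein panel.

    Pipeline: six-frame translation, seeded local alignment of every panel
    query, per (scaffold, strand, query) clustering and chaining, splice
    refinement, ORF completion, then one best model per overlapping locus.
    """
    config = config or GenescanConfig()
    aligner = make_local_aligner()
    matrix = blosum62()

    models = []
    counter = 0
    for scaf_id in sorted(scaffolds):
        seq = scaffolds[scaf_id]
        frames = six_frame_translate(scaf_id, seq)
        coding_by_strand = {"+": seq, "-": revcomp(seq)}
        hits_by_key = defaultdict(list)
        for fr in frames:
            fidx = _kmer_index(fr.peptide, config.seed_length)
            for qid in sorted(panel):
                for h in local_align(qid, panel[qid], fr, config, aligner,
                                     frame_index=fidx, matrix=matrix):
                    hits_by_key[(h.strand, qid)].append(h)
        candidates = []
        for (strand, qid), hits in sorted(hits_by_key.items()):
            hits.sort(key=lambda h: h.c_span)
            clusters = [[hits[0]]]
            for h in hits[1:]:
                if h.c_span[0] - clusters[-1][-1].c_span[1] > config.max_intron:
                    clusters.append([h])
                else:
                    clusters[-1].append(h)
            for cluster in clusters:
                chain, score = chain_hits(cluster, config.max_intron,
                                          config.max_query_overlap)
                if not chain or score < config.min_chain_score:
                    continue
                counter += 1
                m = build_model(chain, score, panel[qid], coding_by_strand[strand],
                                len(seq), config, matrix, model_id=f"{scaf_id}.m{counter}")
                if m is not None and m.protein:
                    candidates.append(m)
        candidates.sort(key=lambda m: (-m.score, m.model_id))
        chosen = []
        for m in candidates:
            if any(_overlap(m.span, c.span) > 0 for c in chosen):
                continue
            chosen.append(m)
        models.extend(chosen)
    return models


def models_to_gff3(models: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.scaffold_id, m.span)):
            s0, s1 = m.span
            attrs = (f"ID={m.model_id};query={m.query_id};score={m.score:.0f};"
                     f"has_start={m.has_start};has_stop={m.has_stop};"
                     f"internal_stops={m.internal_stops}")
            fh.write(f"{m.scaffold_id}\tphotorep\tmRNA\t{s0 + 1}\t{s1}\t{m.score:.0f}\t"
                     f"{m.strand}\t.\t{attrs}\n")
            for s, e in m.exons:
                fh.write(f"{m.scaffold_id}\tphotorep\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                         f"Parent={m.model_id}\n")
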