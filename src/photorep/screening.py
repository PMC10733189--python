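"""Candidate screening: 7-TM architecture, anchor-site lysine, domain profile, ORF.

Implements the three curation criteria used for photopigment reference sets
-- (i) seven transmembrane segments detected by sliding-window hydropathy,
(ii) the chromophore-binding lysine at the anchor-mapped position (K296 in
bovine-rhodopsin numbering, for opsins), (iii) a complete open reading frame
-- plus a family-specific domain-profile score that stands in for a Pfam
domain screen.  Opsins and cryptochrome/photolyases are two configurations
(`FamilyConfig`) of the same screen: CRY-PL configs require their own domain
profiles but no TM segments and no anchor lysine.

Residue numbering is 1-based throughout, matching the bovine-rhodopsin
convention.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from ._seq import AMINO_ACIDS, KD, aligned_blocks, anchor_record, make_global_aligner


class CoordinateError(ValueError):
    pass


class ProfileError(ValueError):
    pass


@dataclass
class FamilyConfig:
    """Screening rules for one protein family."""

    family_name: str
    required_domains: list = field(default_factory=list)
    domain_score_threshold: float = 0.0
    anchor_id: str = "BovineRhodopsin_NP_001014890.1"
    anchor_required_site: tuple | None = (296, "K")  # (position, residue); None disables
    min_tm_segments: int = 7
    min_length: int = 200
    evalue_threshold: float = 1e-20  # recorded for provenance; PSSM screen uses scores
    tm_window: int = 19
    tm_threshold: float = 1.6
    # minimal run of above-threshold windows; 13 is what a 21-residue
    # all-hydrophobic segment flanked by charged loops yields at window 19
    tm_min_run: int = 13

    def __post_init__(self):
        if self.min_tm_segments < 0:
            raise ValueError("min_tm_segments must be >= 0")
        if self.anchor_required_site is not None:
            pos, res = self.anchor_required_site
            if pos < 1:
                raise CoordinateError("anchor position must be >= 1")


def opsin_config(**kw) -> FamilyConfig:
    return FamilyConfig(family_name="opsin", required_domains=["7tm_1 (PF00001.24)"],
                        anchor_required_site=(296, "K"), min_tm_segments=7, **kw)


def cry_pl_config(**kw) -> FamilyConfig:
    return FamilyConfig(family_name="cry_pl",
                        required_domains=["FAD_binding_7 (PF03441.17)", "DNA_photolyase (PF00875.21)"],
                        anchor_required_site=None, min_tm_segments=0, **kw)


# ---------------------------------------------------------------------------
# anchor-position mapping


def map_anchor_position(query: str, anchor: str, anchor_pos: int) -> int | None:
    """Query residue index (1-based) aligned to ``anchor_pos``, or None for a gap.

    Uses a single global affine-gap alignment (BLOSUM62, free end gaps).
    """
    positions = map_anchor_positions(query, anchor, (anchor_pos,))
    return positions[0]


def map_anchor_positions(query: str, anchor: str, anchor_positions) -> list:
    """Map several anchor positions through one shared pairwise alignment."""
    if not query or not anchor:
        raise CoordinateError("empty sequence")
    for p in anchor_positions:
        if not 1 <= p <= len(anchor):
            raise CoordinateError(f"anchor position {p} out of range 1..{len(anchor)}")
    aligner = make_global_aligner()
    aln = aligner.align(anchor, query)[0]
    tb, qb = aligned_blocks(aln)
    out = []
    for p in anchor_positions:
        i = p - 1
        hit = None
        for (ts, te), (qs, qe) in zip(tb, qb):
            if ts <= i < te:
                hit = qs + (i - ts) + 1
                break
        out.append(hit)
    return out


# ---------------------------------------------------------------------------
# transmembrane segment counting


def count_tm_segments(seq: str, window: int = 19, threshold: float = 1.6,
                      min_run: int = 13) -> int:
    """Count maximal runs (>= min_run windows) of high mean Kyte-Doolittle hydropathy."""
    if len(seq) < window:
        return 0
    vals = np.array([KD.get(a, 0.0) for a in seq], dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    means = (csum[window:] - csum[:-window]) / window
    above = means > threshold
    count = 0
    run = 0
    for flag in above:
        if flag:
            run += 1
        else:
            if run >= min_run:
                count += 1
            run = 0
    if run >= min_run:
        count += 1
    return count


# ---------------------------------------------------------------------------
# domain profiles (PSSM over the family master alignment)


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class DomainProfile:
    """Position-specific log-odds scoring profile built from aligned sequences.

    Stands in for a profile-HMM domain screen: the best ungapped-window
    log-odds score of a query against the profile is compared to a
    calibrated threshold.
    """

    name: str
    matrix: np.ndarray  # (L, 20) log2 odds

    @classmethod
    def from_alignment(cls, rows, name: str = "profile", pseudocount: float = 1.0):
        rows = list(rows)
        if len(rows) < 2:
            raise ProfileError("profile needs >= 2 aligned sequences")
        L = len(rows[0])
        if any(len(r) != L for r in rows):
            raise ProfileError("aligned sequences must share one length")
        counts = np.zeros((L, 20))
        bg = np.zeros(20)
        for r in rows:
            for i, a in enumerate(r):
                j = _AA_INDEX.get(a)
                if j is not None:
                    counts[i, j] += 1
                    bg[j] += 1
        if bg.sum() == 0:
            raise ProfileError("profile alignment contains no residues")
        bg = (bg + pseudocount) / (bg.sum() + 20 * pseudocount)
        freq = (counts + pseudocount * bg) / (counts.sum(axis=1, keepdims=True)
                                              + pseudocount)
        matrix = np.log2(freq / bg)
        return cls(name=name, matrix=matrix)

    def score(self, seq: str) -> float:
        """Best ungapped placement of the profile along the query.

        Partial overlaps are allowed (down to half the shorter length) so
        truncated queries are still scoreable.
        """
        L = self.matrix.shape[0]
        idx = np.array([_AA_INDEX.get(a, -1) for a in seq], dtype=int)
        n = len(idx)
        if n == 0:
            return 0.0
        cols = np.where(idx >= 0, self.matrix[:, np.clip(idx, 0, 19)], 0.0)  # (L, n)
        min_overlap = max(1, min(L, n) // 2)
        best = -math.inf
        # S.diagonal(off) holds scores of profile row q-off against query col q
        for off in range(-(L - min_overlap), n - min_overlap + 1):
            d = cols.diagonal(offset=off) if off >= 0 else cols[-off:, :].diagonal()
            if d.size >= min_overlap:
                best = max(best, float(d.sum()))
        return best if best > -math.inf else 0.0


def score_domain(seq: str, profile: DomainProfile) -> float:
    if profile is None or profile.matrix.size == 0:
        raise ProfileError("empty profile")
    return profile.score(seq)


def calibrate_domain_threshold(profile: DomainProfile, n: int = 1000,
                               length: int = 300, seed: int = 0,
                               n_sd: float = 5.0, composition: str | None = None) -> float:
    """mean + n_sd * sd of scores of seeded random sequences (null calibration).

    ``composition`` supplies a residue pool to draw from (composition-
    matched null); default is uniform over the twenty amino acids.
    """
    rng = random.Random(seed)
    pool = composition or AMINO_ACIDS
    scores = [profile.score("".join(rng.choice(pool) for _ in range(length)))
              for _ in range(n)]
    arr = np.array(scores)
    return float(arr.mean() + n_sd * arr.std())


def gathering_threshold(profile: DomainProfile, members, fraction: float = 0.5,
                        null_floor: float | None = None) -> float:
    """Curated cutoff in the style of a Pfam gathering threshold.

    ``fraction`` of the lowest member self-score, never below the
    null-calibrated floor; discriminates sequence *architecture* (a
    reversed member falls far below it) where a pure random-null cutoff
    only discriminates composition.
    """
    lo = min(profile.score(m) for m in members)
    thr = fraction * lo
    if null_floor is not None:
        thr = max(thr, null_floor)
    return thr


# ---------------------------------------------------------------------------
# the combined screen


@dataclass
class ScreenReport:
    seq_id: str
    tm_count: int = 0
    anchor_site_residue: str = "-"
    has_required_site: bool | None = None
    domain_scores: dict = field(default_factory=dict)
    length_ok: bool = False
    orf_complete: bool | None = None  # None = not applicable (protein-only input)
    passed: bool = False
    fail_reasons: list = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "seq_id": self.seq_id, "tm_count": self.tm_count,
            "anchor_site_residue": self.anchor_site_residue,
            "has_required_site": self.has_required_site,
            **{f"score_{k}": round(v, 2) for k, v in self.domain_scores.items()},
            "length_ok": self.length_ok, "orf_complete": self.orf_complete,
            "passed": self.passed, "fail_reasons": ";".join(self.fail_reasons),
        }


def screen_candidate(item, config: FamilyConfig, profiles: dict | None = None,
                     anchor: str | None = None) -> ScreenReport:
    """Apply length, domain, TM, anchor-site and (for gene models) ORF criteria.

    ``item`` is a (seq_id, protein) pair or a genescan ``GeneModel``; all
    criteria are evaluated and recorded even after the first failure.
    """
    from .genescan import GeneModel

    if isinstance(item, GeneModel):
        seq_id, protein = item.model_id, item.protein
        orf_complete = item.has_start and item.has_stop and item.internal_stops == 0
    else:
        seq_id, protein = item
        orf_complete = None

    report = ScreenReport(seq_id=seq_id, orf_complete=orf_complete)
    protein = protein.rstrip("*")

    report.length_ok = len(protein) >= config.min_length
    if not report.length_ok:
        report.fail_reasons.append(f"length<{config.min_length}")

    profiles = profiles or {}
    for dom in config.required_domains:
        prof = profiles.get(dom)
        if prof is None:
            raise ProfileError(f"no profile provided for required domain {dom!r}")
        sc = prof.score(protein)
        report.domain_scores[dom] = sc
        if sc < config.domain_score_threshold:
            report.fail_reasons.append(f"domain_score<{config.domain_score_threshold:.3g}:{dom}")

    report.tm_count = count_tm_segments(protein, config.tm_window,
                                        config.tm_threshold, config.tm_min_run)
    if report.tm_count < config.min_tm_segments:
        report.fail_reasons.append(f"tm_segments<{config.min_tm_segments}")

    if config.anchor_required_site is not None:
        pos, residue = config.anchor_required_site
        if anchor is None:
            anchor = anchor_record()[1]
        qpos = map_anchor_position(protein, anchor, pos) if protein else None
        report.anchor_site_residue = protein[qpos - 1] if qpos else "-"
        report.has_required_site = report.anchor_site_residue == residue
        if not report.has_required_site:
            report.fail_reasons.append(f"missing_{residue}{pos}")

    if orf_complete is False:
        report.fail_reasons.append("orf_incomplete")

    report.passed = not report.fail_reasons
    return report


def screen_set(items, config: FamilyConfig, profiles=None, anchor=None) -> list:
    return [screen_candidate(it, config, profiles=profiles, anchor=anchor) for it in items]
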