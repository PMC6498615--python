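"""Average nucleotide identity estimators and the hybrid distance matrix.

Two self-contained ANI estimators are provided: a fragment-based one in the
spirit of BLAST-based ANIb (the query is cut into ~1 kb windows, each aligned
to its best-matching subject region) and a whole-sequence one in the spirit
of MUMmer-based ANIm (exact-match anchors chained collinearly, inter-anchor
gaps closed by global alignment, identity over matched columns).  The hybrid
distance matrix combines them the way comparative studies of a species
complex do: within-species cells use the ANIm estimate, between-species
cells the ANIb estimate, as 1 - ANI.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .records import CladepanError, GenomeAssembly, LabeledMatrix

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AniParams:
    """Tunable knobs of the ANI estimators.

    The 1020-bp fragment length and the 30% identity / 70% coverage fragment
    retention cutoffs follow the original ANIb convention; ``min_exact_match``
    is the minimum exact-seed length used for ANIm-style chaining.
    """

    fragment_length: int = 1020
    min_fragment_identity: float = 0.30
    min_fragment_coverage: float = 0.70
    seed_kmer: int = 15
    min_exact_match: int = 20
    max_gap_close: int = 5000

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise CladepanError("fragment_length must be >= 100")
        for t in (self.min_fragment_identity, self.min_fragment_coverage):
            if not 0 < t <= 1:
                raise CladepanError("retention thresholds must be in (0, 1]")


@dataclass
class AniPair:
    """Directed ANI between a query and a subject genome.

    ``ani`` is None when no fragment/chain survived (missing, never 0);
    ``aligned_fraction`` is the retained fraction of the query.
    """

    query_id: str
    subject_id: str
    ani: float | None
    aligned_fraction: float


def fragment_sequence(residues: str, fragment_length: int) -> list[str]:
    """Cut into consecutive non-overlapping windows; a final remainder is
    kept only if at least half a fragment long."""
    if not residues:
        raise CladepanError("cannot fragment an empty sequence")
    out = []
    for lo in range(0, len(residues), fragment_length):
        piece = residues[lo: lo + fragment_length]
        if len(piece) == fragment_length or len(piece) * 2 >= fragment_length:
            out.append(piece)
    return out


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i: i + k]].append(i)
    return index


def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """Return (matches, mismatches, insertions_to_query, deletions_from_query)."""
    eq = x = ins = dele = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            eq += n
        elif op == "X":
            x += n
        elif op == "I":
            ins += n
        elif op == "D":
            dele += n
    return eq, x, ins, dele


def _best_fragment_alignment(
    fragment: str,
    subject: str,
    index: dict[str, list[int]],
    params: AniParams,
) -> tuple[float, float] | None:
    """Locate the fragment in the subject by k-mer diagonal voting, then align.

    Returns (identity, coverage) or None when no seed places the fragment.
    """
    k = params.seed_kmer
    votes: Counter[int] = Counter()
    for qpos in range(0, len(fragment) - k + 1, 12):
        for spos in index.get(fragment[qpos: qpos + k], ()):
            votes[(spos - qpos) // 64] += 1
    if not votes:
        return None
    bin_id, _ = votes.most_common(1)[0]
    diag = bin_id * 64
    margin = 96
    lo = max(0, diag - margin)
    hi = min(len(subject), diag + len(fragment) + margin)
    window = subject[lo:hi]
    if not window:
        return None
    res = edlib.align(fragment, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    eq, x, ins, dele = _cigar_stats(res["cigar"])
    columns = eq + x + ins + dele
    if columns == 0:
        return None
    identity = eq / columns
    coverage = (eq + x) / len(fragment)
    return identity, coverage


def anib_pair(
    query: GenomeAssembly,
    subject: GenomeAssembly,
    params: AniParams | None = None,
    _subject_index: dict[str, list[int]] | None = None,
) -> AniPair:
    """Fragment-based ANI: mean identity of retained query fragments.

    Fragments below the identity or coverage retention cutoffs are discarded;
    if nothing is retained, ANI is reported missing with a warning.
    """
    params = params or AniParams()
    subject_seq = "".join(c.residues for c in subject.contigs)
    index = _subject_index if _subject_index is not None else _kmer_index(
        subject_seq, params.seed_kmer
    )
    identities: list[float] = []
    retained_bp = 0
    total_bp = 0
    for contig in query.contigs:
        for fragment in fragment_sequence(contig.residues, params.fragment_length):
            total_bp += len(fragment)
            hit = _best_fragment_alignment(fragment, subject_seq, index, params)
            if hit is None:
                continue
            identity, coverage = hit
            if identity < params.min_fragment_identity or coverage < params.min_fragment_coverage:
                continue
            identities.append(identity)
            retained_bp += len(fragment)
    if not identities:
        warnings.warn(
            f"no retained fragments for {query.genome_id} vs {subject.genome_id}; "
            "ANI recorded as missing",
            stacklevel=2,
        )
        return AniPair(query.genome_id, subject.genome_id, None, 0.0)
    return AniPair(
        query.genome_id,
        subject.genome_id,
        float(np.mean(identities)),
        retained_bp / total_bp if total_bp else 0.0,
    )


def _exact_anchors(
    query: str,
    subject: str,
    params: AniParams,
    index: dict[str, list[int]] | None = None,
) -> list[tuple[int, int, int]]:
    """Collinear exact-match anchors as (qpos, spos, length), merged on-diagonal."""
    k = params.min_exact_match
    if index is None:
        index = _kmer_index(subject, k)
    raw: list[tuple[int, int]] = []
    for qpos in range(0, len(query) - k + 1, k // 2):
        hits = index.get(query[qpos: qpos + k], ())
        if len(hits) == 1:  # keep only unique seeds: repeats are ambiguous
            raw.append((qpos, hits[0]))
    raw.sort()
    # longest increasing subsequence on subject positions => collinear chain
    chain = _lis_chain(raw)
    # merge same-diagonal overlapping/adjacent seeds into maximal blocks
    anchors: list[tuple[int, int, int]] = []
    for qpos, spos in chain:
        if anchors:
            aq, asp, alen = anchors[-1]
            if spos - qpos == asp - aq and qpos <= aq + alen:
                anchors[-1] = (aq, asp, qpos + k - aq)
                continue
        anchors.append((qpos, spos, k))
    return anchors


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing subject positions (patience LIS)."""
    import bisect

    if not pairs:
        return []
    tails: list[int] = []
    tails_idx: list[int] = []
    parent = [-1] * len(pairs)
    for i, (_, spos) in enumerate(pairs):
        j = bisect.bisect_left(tails, spos)
        if j == len(tails):
            tails.append(spos)
            tails_idx.append(i)
        else:
            tails[j] = spos
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1]
    while i >= 0:
        out.append(pairs[i])
        i = parent[i]
    return out[::-1]


def anim_pair(
    query: GenomeAssembly,
    subject: GenomeAssembly,
    params: AniParams | None = None,
    _subject_index: dict[str, list[int]] | None = None,
) -> AniPair:
    """Whole-sequence ANI: chained exact matches with gap closing.

    Identity is identities / matched columns over the chained alignment; gap
    (indel) columns are excluded from the denominator so indel-only
    differences do not depress the estimate.
    """
    params = params or AniParams()
    qseq = "".join(c.residues for c in query.contigs)
    sseq = "".join(c.residues for c in subject.contigs)
    anchors = _exact_anchors(qseq, sseq, params, index=_subject_index)
    if not anchors:
        warnings.warn(
            f"no exact-match chain for {query.genome_id} vs {subject.genome_id}; "
            "ANI recorded as missing",
            stacklevel=2,
        )
        return AniPair(query.genome_id, subject.genome_id, None, 0.0)
    matches = 0
    mismatches = 0
    aligned_q = 0
    prev_q_end = prev_s_end = None
    for qpos, spos, length in anchors:
        if prev_q_end is not None:
            gq = qpos - prev_q_end
            gs = spos - prev_s_end
            if 0 <= gq <= params.max_gap_close and 0 <= gs <= params.max_gap_close and gq + gs > 0:
                if gq == 0 or gs == 0:
                    pass  # pure indel: gap columns excluded entirely
                else:
                    res = edlib.align(
                        qseq[prev_q_end:qpos], sseq[prev_s_end:spos], mode="NW", task="path"
                    )
                    eq, x, _ins, _dele = _cigar_stats(res["cigar"])
                    matches += eq
                    mismatches += x
                aligned_q += gq
        matches += length
        aligned_q += length
        prev_q_end = qpos + length
        prev_s_end = spos + length
    columns = matches + mismatches
    if columns == 0:
        return AniPair(query.genome_id, subject.genome_id, None, 0.0)
    return AniPair(
        query.genome_id,
        subject.genome_id,
        matches / columns,
        min(1.0, aligned_q / len(qseq)),
    )


def ani_matrix(
    genomes: list[GenomeAssembly],
    method: str = "anib",
    params: AniParams | None = None,
) -> LabeledMatrix:
    """Symmetric ANI matrix: mean of the two directed values, unit diagonal.

    Pairs where either direction is missing are flagged as NaN (missing); the
    matrix is still returned.
    """
    if len(genomes) < 2:
        raise CladepanError("need at least 2 genomes")
    if method not in ("anib", "anim"):
        raise CladepanError(f"unknown ANI method {method!r}")
    pair_fn = anib_pair if method == "anib" else anim_pair
    effective = params or AniParams()
    k = effective.seed_kmer if method == "anib" else effective.min_exact_match
    indexes = {
        g.genome_id: _kmer_index("".join(c.residues for c in g.contigs), k)
        for g in genomes
    }
    labels = [g.genome_id for g in genomes]
    n = len(labels)
    cells = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            fwd = pair_fn(genomes[i], genomes[j], params,
                          _subject_index=indexes[labels[j]])
            rev = pair_fn(genomes[j], genomes[i], params,
                          _subject_index=indexes[labels[i]])
            if fwd.ani is None or rev.ani is None:
                value = math.nan
            else:
                value = 0.5 * (fwd.ani + rev.ani)
            cells[i, j] = cells[j, i] = value
    return LabeledMatrix(
        df=pd.DataFrame(cells, index=labels, columns=labels), symmetric=True
    )


def hybrid_distance_matrix(
    anim: LabeledMatrix,
    anib: LabeledMatrix,
    species_label_of: dict[str, str],
) -> LabeledMatrix:
    """1 - ANIm within a species, 1 - ANIb between species; zero diagonal.

    Missing source cells are hard errors because the downstream tree needs a
    complete distance matrix.
    """
    if anim.row_labels != anib.row_labels or anim.col_labels != anib.col_labels:
        raise CladepanError("ANIm and ANIb matrices have different label sets/order")
    labels = anim.row_labels
    missing = [g for g in labels if g not in species_label_of]
    if missing:
        raise CladepanError(f"no species label for genomes: {missing}")
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = species_label_of[labels[i]] == species_label_of[labels[j]]
            src = anim if same else anib
            value = float(src.df.iat[i, j])
            if math.isnan(value):
                raise CladepanError(
                    f"missing {'ANIm' if same else 'ANIb'} value for pair "
                    f"({labels[i]}, {labels[j]})"
                )
            out[i, j] = out[j, i] = 1.0 - value
    return LabeledMatrix(
        df=pd.DataFrame(out, index=labels, columns=labels), symmetric=True
    )
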