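"""Independent brute-force implementations of the scar rules, for oracle tests.

These deliberately avoid the package's region machinery: candidate regions are
enumerated explicitly over every (i, j) segment span and the textual rules are
applied directly.  Slow but simple — correctness over speed.
"""

from __future__ import annotations


def _sorted_chrom_segments(profile):
    by_chrom = {}
    for s in sorted(profile.segments, key=lambda s: (s.chromosome, s.start)):
        by_chrom.setdefault(s.chromosome, []).append(s)
    return by_chrom


def _as_tuples(segs):
    return [(s.start, s.end, s.major_cn, s.minor_cn) for s in segs]


def _merge_same_state(tuples, max_gap):
    """Fuse identical-state neighbours with gaps <= max_gap (rule-text merge)."""
    out = []
    for start, end, major, minor in tuples:
        if (
            out
            and (major, minor) == (out[-1][2], out[-1][3])
            and start - out[-1][1] <= max_gap
        ):
            out[-1] = (out[-1][0], end, major, minor)
        else:
            out.append((start, end, major, minor))
    return out


def _spans(segs, predicate, max_gap):
    """All (i, j) spans of consecutive predicate-true tuples, gaps <= max_gap."""
    n = len(segs)
    spans = []
    for i in range(n):
        if not predicate(segs[i]):
            continue
        for j in range(i, n):
            if not predicate(segs[j]):
                break
            ok = all(
                segs[k + 1][0] - segs[k][1] <= max_gap for k in range(i, j)
            )
            if ok:
                spans.append((i, j))
    return spans


def _is_maximal(segs, i, j, predicate, max_gap):
    if i > 0 and predicate(segs[i - 1]) and segs[i][0] - segs[i - 1][1] <= max_gap:
        return False
    if (
        j + 1 < len(segs)
        and predicate(segs[j + 1])
        and segs[j + 1][0] - segs[j][1] <= max_gap
    ):
        return False
    return True


def _maximal_regions(segs, predicate, max_gap):
    return [
        (segs[i][0], segs[j][1])
        for i, j in _spans(segs, predicate, max_gap)
        if _is_maximal(segs, i, j, predicate, max_gap)
    ]


def oracle_loh(profile, genome, params):
    """Intermediate-size LOH regions, enumerated by brute force."""
    is_loh = lambda t: t[3] == 0 and t[2] >= 1  # noqa: E731
    count = 0
    for chrom, raw in _sorted_chrom_segments(profile).items():
        if chrom not in genome:
            continue
        segs = _merge_same_state(_as_tuples(raw), params.merge_max_gap)
        covered = (segs[0][0], segs[-1][1])
        for start, end in _maximal_regions(segs, is_loh, params.merge_max_gap):
            if end - start <= params.loh_min_len:
                continue
            if (start, end) == covered:
                continue
            count += 1
    return count


def oracle_tai(profile, genome, params):
    """Telomeric allelic-imbalance regions, enumerated by brute force."""
    is_ai = lambda t: t[2] != t[3]  # noqa: E731
    count = 0
    for chrom, raw in _sorted_chrom_segments(profile).items():
        if chrom not in genome:
            continue
        info = genome[chrom]
        segs = _merge_same_state(_as_tuples(raw), params.merge_max_gap)
        first_cov, last_cov = segs[0][0], segs[-1][1]
        for start, end in _maximal_regions(segs, is_ai, params.merge_max_gap):
            p_telo = start <= params.telomere_tolerance or start == first_cov
            q_telo = (
                end >= info.length - params.telomere_tolerance or end == last_cov
            )
            if p_telo == q_telo:  # neither, or whole-chromosome
                continue
            if start < info.centromere_end and end > info.centromere_start:
                continue
            if end - start < params.tai_min_len:
                continue
            count += 1
    return count


def oracle_lst(profile, genome, params):
    """Large-scale state transitions per arm, enumerated by brute force."""
    count = 0
    for chrom, raw in _sorted_chrom_segments(profile).items():
        if chrom not in genome:
            continue
        for lo, hi in genome[chrom].arms:
            clipped = []
            for s in raw:
                a, b = max(s.start, lo), min(s.end, hi)
                if a < b:
                    clipped.append((a, b, s.major_cn, s.minor_cn))
            # fixed-point smoothing: drop short pieces, refuse same-state joins
            segs = clipped
            while True:
                nxt = _merge_same_state(
                    [t for t in segs if t[1] - t[0] >= params.lst_smooth_len],
                    params.lst_smooth_len,
                )
                nxt = [
                    (a, b, ma, mi)
                    for a, b, ma, mi in nxt
                ]
                if nxt == segs:
                    break
                segs = nxt
            for left, right in zip(segs, segs[1:]):
                different = (left[2], left[3]) != (right[2], right[3])
                gap_ok = right[0] - left[1] <= params.lst_smooth_len
                both_large = (
                    left[1] - left[0] >= params.lst_min_seg
                    and right[1] - right[0] >= params.lst_min_seg
                )
                if different and gap_ok and both_large:
                    count += 1
    return count


def oracle_scores(profile, genome, params):
    return (
        oracle_loh(profile, genome, params),
        oracle_tai(profile, genome, params),
        oracle_lst(profile, genome, params),
    )
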