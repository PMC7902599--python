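"""Plant miRNA target-site scoring with an expectation penalty.

The score ("expectation") of a putative site is a sum of per-position
penalties over the antiparallel miRNA:target duplex: 0 for a Watson–Crick
pair, 0.5 for a G:U wobble, 1.0 for a mismatch and 2.0 for a gap (bulge),
with every penalty doubled when the miRNA position (counted from its 5'
end) lies in the seed span 2–13.  Sites are reported when the expectation
is at or below a cutoff (default 3.0).  The regulation mode is called
*cleavage* unless the duplex has any non-Watson–Crick state at the central
miRNA positions 9–11 (where slicing occurs), in which case the site is
predicted to act by *translational inhibition*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}  # A-T, C-G
_WOBBLE = {(2, 3), (3, 2)}  # G:U in either orientation

MATCH, GU, MISMATCH, GAP = "match", "GU", "mismatch", "gap"
_BASE_PENALTY = {MATCH: 0.0, GU: 0.5, MISMATCH: 1.0, GAP: 2.0}

SEED_SPAN = (2, 13)  # miRNA positions (1-based, from 5') with doubled penalties
CENTRAL_SPAN = (9, 11)  # positions deciding cleavage vs translational inhibition

MIN_MIRNA_LEN = 15


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message clarity only
        raise ValueError(f"unexpected base {exc.args[0]!r} in sequence") from None


def pair_state(mirna_base: str, target_base: str) -> str:
    """Duplex state of one miRNA base against the target base it faces."""
    a, b = _CODE[mirna_base.upper().replace("U", "T")], _CODE[
        target_base.upper().replace("U", "T")
    ]
    if a == 4 or b == 4:
        return MISMATCH
    if _COMPLEMENT[a] == b:
        return MATCH
    if (a, b) in _WOBBLE:
        return GU
    return MISMATCH


def _position_weight(mirna_pos: int) -> float:
    return 2.0 if SEED_SPAN[0] <= mirna_pos <= SEED_SPAN[1] else 1.0


def score_alignment(mirna: str, target_site: str) -> float:
    """Expectation of an ungapped duplex of a miRNA with an equal-length site.

    Both sequences are given 5'->3'; the duplex is antiparallel, so miRNA
    position 1 (5' end) faces the last base of the site.
    """
    if len(mirna) != len(target_site):
        raise ValueError("ungapped scoring needs equal-length sequences")
    m = len(mirna)
    total = 0.0
    for i, base in enumerate(mirna):
        pos = i + 1  # 1-based from the miRNA 5' end
        state = pair_state(base, target_site[m - 1 - i])
        total += _BASE_PENALTY[state] * _position_weight(pos)
    return total


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    locus: str
    start: int  # 0-based site start on the target
    end: int
    expectation: float
    mode: str  # cleavage | translational_inhibition
    alignment: str  # one symbol per miRNA 5'->3' position (:=match o=GU .=mismatch -=bulge)


def _alignment_states(
    mirna: str, target: str, start: int, variant: tuple[str, int]
) -> list[str]:
    """Duplex states per miRNA position (1-based order) for one site variant.

    ``variant`` is ('ungapped', -1), ('target_bulge', k) or
    ('mirna_bulge', k) with k an index into the reversed miRNA.
    """
    m = len(mirna)
    mr = mirna[::-1]  # mr[k] faces target[start + k] in the ungapped register
    kind, k = variant
    states: list[tuple[int, str]] = []  # (miRNA 1-based position, state)
    if kind == "ungapped":
        for j in range(m):
            states.append((m - j, pair_state(mr[j], target[start + j])))
    elif kind == "target_bulge":
        for j in range(m):
            t = start + j if j <= k else start + j + 1
            states.append((m - j, pair_state(mr[j], target[t])))
    else:  # mirna_bulge: mr[k] unpaired
        for j in range(m):
            if j == k:
                states.append((m - j, GAP))
            else:
                t = start + j if j < k else start + j - 1
                states.append((m - j, pair_state(mr[j], target[t])))
    return [s for _, s in sorted(states)]  # ordered by miRNA position 1..m


def _mode_from_states(states: list[str]) -> str:
    lo, hi = CENTRAL_SPAN
    central = states[lo - 1: hi]
    return "cleavage" if all(s == MATCH for s in central) else "translational_inhibition"


def _expectation_from_states(states: list[str]) -> float:
    return sum(
        _BASE_PENALTY[s] * _position_weight(pos)
        for pos, s in enumerate(states, start=1)
    )


_SYMBOL = {MATCH: ":", GU: "o", MISMATCH: ".", GAP: "-"}


def scan_target(
    mirna: str,
    target: str,
    expectation_max: float = 3.0,
    max_gaps: int = 1,
) -> tuple[int, float, tuple[str, int]] | None:
    """Best site of one miRNA on one target sequence.

    Returns (start, expectation, variant) for the best-scoring site with
    expectation <= ``expectation_max`` (ties broken toward the 5'-most
    site, then toward the ungapped register), or None.  ``max_gaps`` of 0
    restricts the search to ungapped duplexes; 1 additionally allows a
    single bulge on either strand.
    """
    m, L = len(mirna), len(target)
    if m > L:
        return None
    mr_codes = _encode(mirna)[::-1]
    t_codes = _encode(target)
    weights = np.array([_position_weight(m - j) for j in range(m)])

    # penalty of mr[j] against each target base, seed-weighted
    pen_tab = np.ones((5, 5))  # mismatch default, incl. N rows/cols
    for a in range(4):
        pen_tab[a, _COMPLEMENT[a]] = 0.0
    for a, b in _WOBBLE:
        pen_tab[a, b] = 0.5
    P = pen_tab[mr_codes][np.arange(m)[:, None], t_codes[None, :]] * weights[:, None]

    # A[j, off]: penalty of mr[j] facing target[off + j]; one extra offset
    # column (used only by bulge registers) padded with +inf off the end
    n_sites = L - m + 1
    n_off = n_sites + 1
    A = np.full((m, n_off), np.inf)
    for j in range(m):
        width = min(n_off, L - j)
        A[j, :width] = P[j, j: j + width]

    candidates: list[tuple[float, int, int, tuple[str, int]]] = []
    ungapped = A[:, :n_sites].sum(axis=0)
    for s in np.flatnonzero(ungapped <= expectation_max):
        candidates.append((float(ungapped[s]), int(s), 0, ("ungapped", -1)))

    if max_gaps >= 1 and m >= 2:
        pre = np.cumsum(A, axis=0)  # pre[k, s] = sum_{j<=k} A[j, s]
        suf = np.cumsum(A[::-1], axis=0)[::-1]  # suf[k, s] = sum_{j>=k} A[j, s]
        # one unpaired target base between register positions k and k+1:
        # mr[0..k] at offset s, mr[k+1..] at offset s+1; site spans m+1 bases
        if L - m >= 1:
            for k in range(m - 1):
                gp = 2.0 * _position_weight(m - k - 1)
                sc = pre[k, : L - m] + suf[k + 1, 1: L - m + 1] + gp
                for s in np.flatnonzero(sc <= expectation_max):
                    candidates.append((float(sc[s]), int(s), 1, ("target_bulge", k)))
        # one unpaired miRNA base at register position k; site spans m-1 bases
        for k in range(1, m - 1):
            gp = 2.0 * _position_weight(m - k)
            sc = pre[k - 1, 1:n_off] + suf[k + 1, : n_off - 1] + gp
            for i in np.flatnonzero(sc <= expectation_max):
                candidates.append((float(sc[i]), int(i) + 1, 2, ("mirna_bulge", k)))
            # a site flush with the target 5' end needs offset -1 for the
            # post-bulge segment, which the matrix cannot hold; score directly
            sc0 = float(pre[k - 1, 0]) + gp + sum(
                float(P[j, j - 1]) for j in range(k + 1, m)
            )
            if sc0 <= expectation_max:
                candidates.append((sc0, 0, 2, ("mirna_bulge", k)))

    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    score, start, _, variant = candidates[0]
    return start, score, variant


def find_targets(
    mirnas: dict[str, str],
    sequences: dict[str, str],
    expectation_max: float = 3.0,
    max_gaps: int = 1,
) -> list[TargetHit]:
    """Best-scoring site per (miRNA, locus) with expectation <= the cutoff."""
    hits: list[TargetHit] = []
    for mirna_id, mseq in sorted(mirnas.items()):
        mseq = mseq.upper().replace("U", "T")
        if len(mseq) < MIN_MIRNA_LEN:
            raise ValueError(
                f"{mirna_id}: miRNA of {len(mseq)} nt is shorter than the "
                f"{MIN_MIRNA_LEN} nt minimum"
            )
        for locus, tseq in sorted(sequences.items()):
            tseq = tseq.upper().replace("U", "T")
            found = scan_target(mseq, tseq, expectation_max, max_gaps)
            if found is None:
                continue
            start, score, variant = found
            states = _alignment_states(mseq, tseq, start, variant)
            site_len = len(mseq) + (1 if variant[0] == "target_bulge" else 0) - (
                1 if variant[0] == "mirna_bulge" else 0
            )
            hits.append(
                TargetHit(
                    mirna_id=mirna_id,
                    locus=locus,
                    start=start,
                    end=start + site_len,
                    expectation=score,
                    mode=_mode_from_states(states),
                    alignment="".join(_SYMBOL[s] for s in states),
                )
            )
    return hits
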