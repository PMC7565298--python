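"""Seed-constrained miRNA:3'UTR duplex prediction.

The screen mirrors the classical hybridization approach: a candidate
site must contain a perfect Watson-Crick match to the miRNA seed
(positions 2-8 from the miRNA 5' end, G:U wobble disallowed inside the
seed), and the duplex formed by extending that seed helix must reach a
minimum free energy at or below a threshold (default -18 kcal/mol).

The duplex energy is computed by a dynamic program over purely
intermolecular, antiparallel pairings: neither strand folds on itself,
bulges are limited to ``max_bulge`` nucleotides and internal loops to
``max_internal`` nucleotides per side (both default 9). Positions 2-8 of
the miRNA are forced to pair contiguously (the anchoring helix);
position 1 and positions >= 9 pair only where that lowers the energy.
G:U pairs are allowed outside the seed. Coordinates are 1-based and
inclusive on the sense strand of the UTR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .energy import DEFAULT_MODEL, WATSON_CRICK, EnergyModel

_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def normalize_rna(seq: str) -> str:
    """Uppercase, DNA->RNA (T->U); rejects characters outside A/C/G/U/T."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    s = normalize_rna(seq)
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(s))


def find_seed_sites(utr: str, mirna: str, seed_start: int = 2, seed_end: int = 8) -> list[int]:
    """1-based UTR start positions of perfect Watson-Crick seed matches.

    The match motif is the reverse complement of miRNA positions
    ``seed_start..seed_end`` (1-based from the 5' end). G:U is not a
    match: only the exact complement motif counts.
    """
    mi = normalize_rna(mirna)
    if len(mi) < seed_end:
        raise ValueError(f"miRNA shorter than seed end ({len(mi)} < {seed_end})")
    u = normalize_rna(utr)
    motif = reverse_complement(mi[seed_start - 1 : seed_end])
    sites = []
    start = 0
    while True:
        idx = u.find(motif, start)
        if idx < 0:
            break
        sites.append(idx + 1)
        start = idx + 1
    return sites


@dataclass(frozen=True)
class DuplexStructure:
    """Optimal duplex for one window: energy, pairs and a printable form.

    ``pairs`` holds (miRNA position, window position), both 1-based,
    sorted by miRNA position (window positions strictly decreasing:
    the strands are antiparallel).
    """

    mfe: float
    pairs: tuple[tuple[int, int], ...]
    pairing: str

    @property
    def is_hit(self) -> bool:
        return math.isfinite(self.mfe)


NO_STRUCTURE = DuplexStructure(math.inf, (), "")


def _link_cost(
    model: EnergyModel,
    mi: str,
    win: str,
    prev: tuple[int, int],
    cur: tuple[int, int],
    max_bulge: int,
    max_internal: int,
) -> float | None:
    """Energy of joining consecutive pairs ``prev`` -> ``cur``.

    Returns None when the join violates the loop limits. ``prev`` has
    the smaller miRNA index; window indices run the other way.
    """
    a = cur[0] - prev[0] - 1  # unpaired miRNA bases between the pairs
    b = prev[1] - cur[1] - 1  # unpaired window bases
    if a < 0 or b < 0:
        return None
    if a == 0 and b == 0:
        return model.stack_energy(mi[prev[0] - 1], mi[cur[0] - 1], win[prev[1] - 1], win[cur[1] - 1])
    if b == 0:
        return model.bulge_penalty(a) if a <= max_bulge else None
    if a == 0:
        return model.bulge_penalty(b) if b <= max_bulge else None
    if a <= max_internal and b <= max_internal:
        return model.internal_penalty(a, b)
    return None


def score_structure(
    pairs: Sequence[tuple[int, int]],
    mirna: str,
    window: str,
    model: EnergyModel = DEFAULT_MODEL,
    max_bulge: int = 9,
    max_internal: int = 9,
) -> float:
    """Free energy of an explicit pairing; independent of the DP.

    Validates antiparallel monotonicity, pairability and loop limits,
    then sums initiation, stacks, loop penalties and terminal-end
    corrections. Raises ValueError on an illegal structure.
    """
    if not pairs:
        raise ValueError("empty structure")
    mi, win = normalize_rna(mirna), normalize_rna(window)
    ordered = sorted(pairs)
    for i, j in ordered:
        if not (1 <= i <= len(mi) and 1 <= j <= len(win)):
            raise ValueError(f"pair {(i, j)} out of bounds")
        if not model.pairable(mi[i - 1], win[j - 1]):
            raise ValueError(f"unpairable bases at {(i, j)}")
    energy = model.init
    energy += model.terminal_penalty(mi[ordered[0][0] - 1], win[ordered[0][1] - 1])
    energy += model.terminal_penalty(mi[ordered[-1][0] - 1], win[ordered[-1][1] - 1])
    for prev, cur in zip(ordered, ordered[1:]):
        if cur[1] >= prev[1]:
            raise ValueError("window positions must strictly decrease (antiparallel)")
        cost = _link_cost(model, mi, win, prev, cur, max_bulge, max_internal)
        if cost is None:
            raise ValueError(f"loop between {prev} and {cur} violates limits")
        energy += cost
    return energy


def _pairing_string(pairs: Sequence[tuple[int, int]], mi_len: int, win_len: int) -> str:
    mi_line = ["."] * mi_len
    win_line = ["."] * win_len
    for i, j in pairs:
        mi_line[i - 1] = "("
        win_line[j - 1] = ")"
    return "".join(mi_line) + "&" + "".join(win_line)


def _duplex_mfe_free(
    win: str,
    mi: str,
    model: EnergyModel,
    max_bulge: int,
    max_internal: int,
) -> DuplexStructure:
    """Unconstrained intermolecular duplex DP (no forced helix)."""
    m, L = len(mi), len(win)
    # D[(i, j)] = best energy of a duplex whose 3'-most miRNA pair is (i, j),
    # including initiation and the terminal correction at its first pair.
    D: dict[tuple[int, int], float] = {}
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    reach = max(max_bulge, max_internal) + 1
    for i in range(1, m + 1):
        for j in range(L, 0, -1):
            if not model.pairable(mi[i - 1], win[j - 1]):
                continue
            best = model.init + model.terminal_penalty(mi[i - 1], win[j - 1])
            origin: tuple[int, int] | None = None
            for ip in range(max(1, i - reach), i):
                for jp in range(j + 1, min(L, j + reach) + 1):
                    prev_e = D.get((ip, jp))
                    if prev_e is None:
                        continue
                    cost = _link_cost(model, mi, win, (ip, jp), (i, j), max_bulge, max_internal)
                    if cost is None:
                        continue
                    if prev_e + cost < best:
                        best = prev_e + cost
                        origin = (ip, jp)
            D[(i, j)] = best
            back[(i, j)] = origin
    if not D:
        return NO_STRUCTURE
    end, e = min(
        D.items(), key=lambda kv: (kv[1] + model.terminal_penalty(mi[kv[0][0] - 1], win[kv[0][1] - 1]), kv[0])
    )
    mfe = e + model.terminal_penalty(mi[end[0] - 1], win[end[1] - 1])
    pairs = []
    cur: tuple[int, int] | None = end
    while cur is not None:
        pairs.append(cur)
        cur = back[cur]
    pairs.reverse()
    return DuplexStructure(mfe, tuple(pairs), _pairing_string(pairs, m, L))


def _duplex_mfe_anchored(
    win: str,
    mi: str,
    model: EnergyModel,
    max_bulge: int,
    max_internal: int,
    seed_start: int,
    seed_end: int,
) -> DuplexStructure:
    """DP with miRNA positions seed_start..seed_end forced into a helix."""
    m, L = len(mi), len(win)
    sites = find_seed_sites(win, mi, seed_start, seed_end)
    best = NO_STRUCTURE
    span = seed_end - seed_start  # 6 for the canonical 2-8 seed
    for s in sites:
        # seed helix: miRNA position k pairs window position s + span - (k - seed_start)
        seed_pairs = [(k, s + span - (k - seed_start)) for k in range(seed_start, seed_end + 1)]
        energy = model.init
        for prev, cur in zip(seed_pairs, seed_pairs[1:]):
            energy += model.stack_energy(mi[prev[0] - 1], mi[cur[0] - 1], win[prev[1] - 1], win[cur[1] - 1])

        # 5' side: miRNA positions < seed_start (position 1 for the 2-8 seed)
        # pair window positions > s + span, nearest-first.
        first_pair = seed_pairs[0]
        left_best = model.terminal_penalty(mi[first_pair[0] - 1], win[first_pair[1] - 1])
        left_pairs: list[tuple[int, int]] = []
        if seed_start > 1:
            i = seed_start - 1
            for j in range(first_pair[1] + 1, min(L, first_pair[1] + max_bulge + 1) + 1):
                if not model.pairable(mi[i - 1], win[j - 1]):
                    continue
                cost = _link_cost(model, mi, win, (i, j), first_pair, max_bulge, max_internal)
                if cost is None:
                    continue
                cand = cost + model.terminal_penalty(mi[i - 1], win[j - 1])
                if cand < left_best:
                    left_best = cand
                    left_pairs = [(i, j)]

        # 3' side: miRNA positions > seed_end extend toward window position 1.
        last_pair = seed_pairs[-1]
        E: dict[tuple[int, int], float] = {}
        back: dict[tuple[int, int], tuple[int, int] | None] = {}
        reach = max(max_bulge, max_internal) + 1
        for i in range(seed_end + 1, m + 1):
            for j in range(last_pair[1] - 1, 0, -1):
                if not model.pairable(mi[i - 1], win[j - 1]):
                    continue
                val: float | None = None
                origin: tuple[int, int] | None = None
                base = _link_cost(model, mi, win, last_pair, (i, j), max_bulge, max_internal)
                if base is not None:
                    val = base
                for ip in range(max(seed_end + 1, i - reach), i):
                    for jp in range(j + 1, min(last_pair[1] - 1, j + reach) + 1):
                        prev_e = E.get((ip, jp))
                        if prev_e is None:
                            continue
                        cost = _link_cost(model, mi, win, (ip, jp), (i, j), max_bulge, max_internal)
                        if cost is None:
                            continue
                        if val is None or prev_e + cost < val:
                            val = prev_e + cost
                            origin = (ip, jp)
                if val is not None:
                    E[(i, j)] = val
                    back[(i, j)] = origin
        right_best = model.terminal_penalty(mi[last_pair[0] - 1], win[last_pair[1] - 1])
        right_end: tuple[int, int] | None = None
        for (i, j), e in E.items():
            cand = e + model.terminal_penalty(mi[i - 1], win[j - 1])
            if cand < right_best:
                right_best = cand
                right_end = (i, j)
        right_pairs: list[tuple[int, int]] = []
        cur = right_end
        while cur is not None:
            right_pairs.append(cur)
            cur = back[cur]
        right_pairs.reverse()

        total = energy + left_best + right_best
        if total < best.mfe:
            pairs = tuple(left_pairs + seed_pairs + right_pairs)
            best = DuplexStructure(total, pairs, _pairing_string(pairs, m, L))
    return best


def duplex_mfe(
    utr_window: str,
    mirna: str,
    model: EnergyModel = DEFAULT_MODEL,
    max_bulge: int = 9,
    max_internal: int = 9,
    helix_constraint: tuple[int, int] | None = (2, 8),
) -> DuplexStructure:
    """Minimum-free-energy intermolecular duplex for a window.

    With the default ``helix_constraint`` (2, 8) the miRNA seed must be
    contiguously paired at a perfect-complement site inside the window;
    if no such site exists the sentinel with ``mfe == +inf`` is
    returned. ``helix_constraint=None`` computes the unconstrained
    duplex MFE (used for oracle comparison and diagnostics).
    """
    mi = normalize_rna(mirna)
    win = normalize_rna(utr_window)
    if helix_constraint is None:
        return _duplex_mfe_free(win, mi, model, max_bulge, max_internal)
    seed_start, seed_end = helix_constraint
    if len(mi) < seed_end:
        raise ValueError("miRNA shorter than helix constraint end")
    return _duplex_mfe_anchored(win, mi, model, max_bulge, max_internal, seed_start, seed_end)


@dataclass(frozen=True)
class DuplexHit:
    """One retained (miRNA, UTR, site) prediction."""

    mirna_id: str
    utr_id: str
    seed_pos: int  # 1-based UTR start of the seed match
    site_start: int  # 1-based first paired UTR position
    site_end: int  # 1-based last paired UTR position
    mfe: float
    pairing: str
    seed_anchored: bool = True


def predict_targets(
    mirnas: Mapping[str, str],
    utrs: Mapping[str, str],
    model: EnergyModel = DEFAULT_MODEL,
    mfe_threshold: float = -18.0,
    max_bulge: int = 9,
    max_internal: int = 9,
) -> list[DuplexHit]:
    """Screen every miRNA against every UTR.

    A hit requires a perfect seed match plus duplex MFE <= threshold
    (inclusive). Overlapping hits of the same (miRNA, UTR) pair are
    collapsed to the lowest-MFE site. UTRs shorter than the seed are
    skipped.
    """
    if not mirnas or not utrs:
        raise ValueError("empty miRNA or UTR input")
    hits: list[DuplexHit] = []
    for mid, mseq in mirnas.items():
        mi = normalize_rna(mseq)
        mlen = len(mi)
        for uid, useq in utrs.items():
            u = normalize_rna(useq)
            if len(u) < 7:
                continue
            pair_hits: list[DuplexHit] = []
            for s in find_seed_sites(u, mi):
                lo = max(0, s - 1 - (mlen + 9))
                hi = min(len(u), s + 6 + (mlen + 9))
                window = u[lo:hi]
                st = duplex_mfe(window, mi, model, max_bulge, max_internal)
                if not st.is_hit or st.mfe > mfe_threshold:
                    continue
                win_positions = [j for _, j in st.pairs]
                pair_hits.append(
                    DuplexHit(
                        mirna_id=mid,
                        utr_id=uid,
                        seed_pos=s,
                        site_start=lo + min(win_positions),
                        site_end=lo + max(win_positions),
                        mfe=st.mfe,
                        pairing=st.pairing,
                    )
                )
            hits.extend(_collapse_overlaps(pair_hits))
    return hits


def _collapse_overlaps(pair_hits: Iterable[DuplexHit]) -> list[DuplexHit]:
    kept: list[DuplexHit] = []
    for hit in sorted(pair_hits, key=lambda h: (h.mfe, h.seed_pos)):
        if all(hit.site_end < k.site_start or hit.site_start > k.site_end for k in kept):
            kept.append(hit)
    return sorted(kept, key=lambda h: h.seed_pos)


def seed_is_watson_crick(mirna: str, utr_site: str) -> bool:
    """True when the 7-mer site is the exact seed reverse complement."""
    mi = normalize_rna(mirna)
    site = normalize_rna(utr_site)
    if len(site) != 7:
        return False
    return all((a, b) in WATSON_CRICK for a, b in zip(mi[1:8], reversed(site)))
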