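"""Independent re-derivations of rule decisions, used to cross-check results.

Everything here is written as plain, direct code over the raw sequences and
dot-bracket strings, deliberately sharing no logic with the vectorised
scanner in :mod:`mirwood.targets` or the candidate construction in
:mod:`mirwood.discovery`, so that a disagreement points at a real defect.
"""

from __future__ import annotations

from . import structure
from ._seq import transcribe

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def position_weights(mirna: str, site: str) -> list[float]:
    """Weights per miRNA position, recomputed character by character."""
    mirna = transcribe(mirna.upper())
    site = transcribe(site.upper())
    if len(mirna) != len(site):
        raise ValueError("length mismatch")
    out = []
    n = len(site)
    for k, mb in enumerate(mirna):          # k = miRNA position - 1
        sb = site[n - 1 - k]
        if (mb, sb) in _WC:
            out.append(0.0)
        elif (mb, sb) in _WOBBLE:
            out.append(0.5)
        else:
            out.append(1.0)
    return out


def check_target_rules(mirna: str, site: str,
                       rules=None) -> dict[str, bool]:
    """Rules 1-5 decided by direct enumeration of the definition of each rule."""
    from .targets import DEFAULT_RULES

    rules = rules or DEFAULT_RULES
    w = position_weights(mirna, site)
    n = len(w)
    res = {}
    res["rule1_total"] = sum(w) <= rules.max_total + 1e-9
    thresh = 0.5 if rules.adjacency_counts_gu else 1.0
    longest = cur = 0
    for x in w:
        cur = cur + 1 if x >= thresh else 0
        longest = max(longest, cur)
    res["rule2_adjacent"] = longest <= rules.max_adjacent_run
    lo = 1.0 if rules.rule3_full_only else thresh
    res["rule3_seed_adjacent"] = True
    for pos in range(2, 12):                 # 1-based pairs (pos, pos+1), both <= 12
        if w[pos - 1] >= lo and w[pos] >= lo:
            res["rule3_seed_adjacent"] = False
            break
    bad = 0.0 if rules.rule4_strict_gu else 0.5
    res["rule4_cleavage"] = w[9] <= bad and w[10] <= bad
    res["rule5_seed_total"] = sum(w[:12]) <= rules.max_seed_total + 1e-9
    res["passes_rules"] = all(res.values())
    return res


def revalidate_hairpin(precursor: str, mature: str, structure_db: str,
                       copies: int, config=None) -> dict[str, bool]:
    """Re-derive the novel-miRNA structural criteria from precursor + structure.

    Works directly on the dot-bracket string: partner map, star interval with
    the 2-nt 3' overhang, spacing, largest bulge, duplex asymmetry, the single
    stem-loop requirement and the length/copy/MFE bounds.
    """
    from .discovery import DEFAULT_DISCOVERY

    cfg = config or DEFAULT_DISCOVERY
    pre = transcribe(precursor.upper())
    mat = transcribe(mature.upper())
    res: dict[str, bool] = {}
    res["mature_min_len"] = len(mat) >= cfg.mature_len_min
    res["mature_max_len"] = len(mat) <= cfg.mature_len_max
    res["max_copies"] = copies <= cfg.max_copies
    mstart = pre.find(mat)
    if mstart < 0:
        res["mature_in_precursor"] = False
        res["all"] = False
        return res
    res["mature_in_precursor"] = True
    mend = mstart + len(mat) - 1

    partner: dict[int, int] = {}
    stack = []
    for i, c in enumerate(structure_db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i], partner[j] = j, i

    e = structure.structure_energy(pre, structure_db)
    res["precursor_mfe"] = e <= cfg.precursor_mfe_max + 1e-9

    # single hairpin loop: exactly one maximal run of dots enclosed by a pair
    closings = 0
    for i, j in sorted((min(i, j), max(i, j)) for i, j in partner.items() if i < j):
        if all(structure_db[k] == "." for k in range(i + 1, j)):
            closings += 1
    res["single_stemloop"] = closings == 1

    # arm of the mature
    arm = "none"
    if closings == 1:
        hi, hj = next((i, j) for i, j in sorted(
            (min(i, j), max(i, j)) for i, j in partner.items() if i < j)
            if all(structure_db[k] == "." for k in range(i + 1, j)))
        if mend <= hi:
            arm = "5p"
        elif mstart >= hj:
            arm = "3p"
    res["mature_on_one_arm"] = arm in ("5p", "3p")

    # star interval by Dicer geometry (2-nt 3' overhangs)
    paired_m = [p for p in range(mstart, mend + 1) if p in partner]
    if not paired_m:
        res["all"] = False
        return res
    partners = [partner[p] for p in paired_m]
    star_lo, star_hi = min(partners), max(partners) + 2
    star_hi = min(star_hi, len(pre) - 1)
    star_len = star_hi - star_lo + 1
    res["star_min_len"] = star_len >= cfg.star_len_min
    res["star_max_len"] = star_len <= cfg.star_len_max
    if arm == "5p":
        spacing = star_lo - mend - 1
    else:
        spacing = mstart - star_hi - 1
    res["spacing_min"] = spacing >= cfg.spacing_min
    res["spacing_max"] = spacing <= cfg.spacing_max

    # bulges and asymmetry inside the mature/star duplex
    bulge_max = 0
    for a, b in zip(paired_m, paired_m[1:]):
        gap_m = b - a - 1
        gap_s = abs(partner[a] - partner[b]) - 1
        bulge_max = max(bulge_max, gap_m, gap_s)
    unp_m = (paired_m[-1] - paired_m[0] + 1) - len(paired_m)
    unp_s = (max(partners) - min(partners) + 1) - len(partners)
    res["max_bulge"] = bulge_max <= cfg.max_bulge
    res["max_asymmetry"] = abs(unp_m - unp_s) <= cfg.max_asymmetry
    res["all"] = all(res.values())
    return res
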