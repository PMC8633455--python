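"""RNA secondary-structure folding and duplex hybridisation energies.

Hairpin candidates are screened with a single-strand minimum-free-energy
fold (:func:`fold`), and miRNA/target binding strength with an intermolecular
duplex fold (:func:`duplex_mfe`).  Both use the same simplified
nearest-neighbour energy model: stacking energies per adjacent base pair
(AU, UA, GC, CG plus the G:U wobbles), log-linear hairpin/bulge/internal-loop
penalties and an affine multiloop cost.  The model is deliberately
self-contained: every threshold applied downstream (precursor stability,
MFE-ratio of target sites) is defined relative to this model, and reference
routines (:func:`structure_energy`, :func:`enumerate_structures`,
:func:`enumerate_duplex_energy`) allow any folded result to be re-derived by
exhaustive enumeration on small instances.

Minimum hairpin loop is 3 nt; lonely pairs are allowed; interior loops are
capped at 30 unpaired nt.  Ties between equal-energy structures are broken by
a fixed traceback order (hairpin closure, then interior closures by ascending
coordinates, then multiloop), so folding is deterministic across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterator

import numpy as np

from ._fold_kernels import INF, MAXLOOP, MIN_HAIRPIN, PAIR_TYPE, duplex_dp, fold_dp
from ._seq import encode, revcomp_rna, transcribe

log = logging.getLogger(__name__)

_EPS = 1e-9

PAIR_ORDER = ("AU", "UA", "GC", "CG", "GU", "UG")


def _load_default_stack() -> np.ndarray:
    txt = resources.files("mirwood.data").joinpath("stack_energies.tsv").read_text()
    rows = [line.split("\t") for line in txt.strip().splitlines()]
    header = rows[0][1:]
    assert tuple(header) == PAIR_ORDER
    return np.array([[float(x) for x in r[1:]] for r in rows[1:]], dtype=np.float64)


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbour parameters, kcal/mol.

    ``stack[p, q]`` is the energy of pair type ``q`` stacked directly inside
    pair type ``p`` (pair-type order: AU UA GC CG GU UG).  Loop penalties are
    ``a + b * ln(size / ref)`` with ref 3 for hairpins, 1 for bulges and 2 for
    internal loops; multiloops cost ``ml_a + ml_b * branches + ml_c * unpaired``
    (the closing pair counts as a branch).
    """

    stack: np.ndarray = field(default_factory=_load_default_stack)
    hp_a: float = 4.5
    hp_b: float = 1.6
    bu_a: float = 3.6
    bu_b: float = 1.1
    in_a: float = 2.6
    in_b: float = 1.2
    ml_a: float = 4.6
    ml_b: float = 0.4
    ml_c: float = 0.2

    def hairpin(self, size: int) -> float:
        return self.hp_a + self.hp_b * np.log(size / 3.0)

    def bulge(self, size: int) -> float:
        return self.bu_a + self.bu_b * np.log(float(size))

    def internal(self, l1: int, l2: int) -> float:
        return self.in_a + self.in_b * np.log((l1 + l2) / 2.0)

    def loop(self, l1: int, l2: int, pt_outer: int, pt_inner: int) -> float:
        if l1 == 0 and l2 == 0:
            return float(self.stack[pt_outer, pt_inner])
        if l1 + l2 > MAXLOOP:
            return INF
        if l1 == 0 or l2 == 0:
            return self.bulge(l1 + l2)
        return self.internal(l1, l2)


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class FoldResult:
    """A single-strand fold: sequence, dot-bracket structure and MFE (kcal/mol)."""

    seq: str
    structure: str
    mfe: float

    def pairs(self) -> list[tuple[int, int]]:
        return parse_dotbracket(self.structure)


@dataclass(frozen=True)
class DuplexResult:
    """An intermolecular hybrid of two strands (both given 5'->3')."""

    strand_a: str
    strand_b: str
    pairing: tuple[tuple[int, int], ...]
    mfe: float


def _prepare(seq: str, what: str) -> str:
    seq = seq.upper()
    if "T" in seq:
        log.info("%s contains T; transcribing to U", what)
        seq = transcribe(seq)
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return seq


def parse_dotbracket(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= 1e-7


def fold(seq: str, model: EnergyModel = DEFAULT_MODEL) -> FoldResult:
    """Minimum-free-energy structure of a single RNA strand (10-500 nt)."""
    seq = _prepare(seq, "fold sequence")
    n = len(seq)
    if not 10 <= n <= 500:
        raise ValueError(f"fold expects 10-500 nt, got {n}")
    arr = encode(seq)
    mfe, V, WM = fold_dp(arr, model.stack, model.hp_a, model.hp_b, model.bu_a,
                         model.bu_b, model.in_a, model.in_b, model.ml_a,
                         model.ml_b, model.ml_c)
    structure = ["."] * n
    if mfe < -_EPS:
        _traceback_external(arr, V, WM, model, structure)
    return FoldResult(seq=seq, structure="".join(structure), mfe=float(mfe))


def _traceback_external(arr, V, WM, model, structure) -> None:
    n = arr.shape[0]
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for k in range(0, j):
            left = W[k - 1] if k > 0 else 0.0
            if V[k, j] < INF and left + V[k, j] < best:
                best = left + V[k, j]
        W[j] = best
    j = n - 1
    while j >= 0:
        target = W[j]
        if _close(target, W[j - 1] if j > 0 else 0.0):
            j -= 1
            continue
        placed = False
        for k in range(0, j + 1):
            left = W[k - 1] if k > 0 else 0.0
            if V[k, j] < INF and _close(left + V[k, j], target):
                _traceback_v(arr, V, WM, model, structure, k, j)
                j = k - 1
                placed = True
                break
        if not placed:  # numerical safety; should not happen
            j -= 1


def _pt(arr, i, j) -> int:
    return int(PAIR_TYPE[arr[i], arr[j]])


def _traceback_v(arr, V, WM, model, structure, i, j) -> None:
    structure[i], structure[j] = "(", ")"
    target = V[i, j]
    if _close(target, model.hairpin(j - i - 1)):
        return
    kmax = min(j - 1, i + MAXLOOP + 1)
    for k in range(i + 1, kmax + 1):
        l1 = k - i - 1
        lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - l1))
        for l in range(lmin, j):
            if V[k, l] >= INF:
                continue
            e = model.loop(l1, j - l - 1, _pt(arr, i, j), _pt(arr, k, l))
            if _close(V[k, l] + e, target):
                _traceback_v(arr, V, WM, model, structure, k, l)
                return
    for k in range(i + 1, j - 1):
        if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
            if _close(model.ml_a + model.ml_b + WM[i + 1, k] + WM[k + 1, j - 1], target):
                _traceback_wm(arr, V, WM, model, structure, i + 1, k)
                _traceback_wm(arr, V, WM, model, structure, k + 1, j - 1)
                return
    raise AssertionError("traceback failed: inconsistent DP matrices")


def _traceback_wm(arr, V, WM, model, structure, i, j) -> None:
    target = WM[i, j]
    if V[i, j] < INF and _close(target, V[i, j] + model.ml_b):
        _traceback_v(arr, V, WM, model, structure, i, j)
        return
    if WM[i + 1, j] < INF and _close(target, WM[i + 1, j] + model.ml_c):
        _traceback_wm(arr, V, WM, model, structure, i + 1, j)
        return
    if WM[i, j - 1] < INF and _close(target, WM[i, j - 1] + model.ml_c):
        _traceback_wm(arr, V, WM, model, structure, i, j - 1)
        return
    for k in range(i + 1, j + 1):
        if WM[i, k - 1] < INF and WM[k, j] < INF and _close(target, WM[i, k - 1] + WM[k, j]):
            _traceback_wm(arr, V, WM, model, structure, i, k - 1)
            _traceback_wm(arr, V, WM, model, structure, k, j)
            return
    raise AssertionError("traceback failed in multiloop segment")


def duplex_mfe(a: str, b: str, model: EnergyModel = DEFAULT_MODEL) -> DuplexResult:
    """Optimal intermolecular hybridisation of two strands, no intramolecular pairs.

    Pairing is antiparallel and monotone (no pseudoknots): if (i, j) and
    (i', j') are pairs with i < i', then j > j'.
    """
    a = _prepare(a, "duplex strand a")
    b = _prepare(b, "duplex strand b")
    if not a or not b:
        raise ValueError("duplex strands must be non-empty")
    if len(a) > 40 or len(b) > 40:
        raise ValueError("duplex strands must be <= 40 nt")
    aa, bb = encode(a), encode(b)
    mfe, E = duplex_dp(aa, bb, model.stack, model.bu_a, model.bu_b, model.in_a, model.in_b)
    pairing: list[tuple[int, int]] = []
    if mfe < -_EPS:
        # rightmost pair of the optimal chain: first (i, j) achieving the MFE
        start = None
        for i in range(len(a)):
            for j in range(len(b)):
                if E[i, j] < INF and _close(E[i, j], mfe):
                    start = (i, j)
                    break
            if start:
                break
        i, j = start
        while True:
            pairing.append((i, j))
            if _close(E[i, j], 0.0):
                break
            found = False
            for ip in range(max(0, i - MAXLOOP - 1), i):
                l1 = i - ip - 1
                for jp in range(j + 1, min(len(b) - 1, j + 1 + (MAXLOOP - l1)) + 1):
                    if E[ip, jp] >= INF:
                        continue
                    e = model.loop(l1, jp - j - 1, _pt_duplex(aa, bb, ip, jp),
                                   _pt_duplex(aa, bb, i, j))
                    if _close(E[ip, jp] + e, E[i, j]):
                        i, j = ip, jp
                        found = True
                        break
                if found:
                    break
            if not found:
                break
        pairing.sort()
    return DuplexResult(strand_a=a, strand_b=b, pairing=tuple(pairing), mfe=float(mfe))


def _pt_duplex(aa, bb, i, j) -> int:
    return int(PAIR_TYPE[aa[i], bb[j]])


def perfect_duplex_mfe(mirna: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """MFE of a miRNA hybridised to its exact reverse complement."""
    mirna = _prepare(mirna, "miRNA")
    return duplex_mfe(mirna, revcomp_rna(mirna), model).mfe


def is_stemloop(fold_result: FoldResult, tag: str) -> tuple[bool, str]:
    """Check the perfect stem-loop requirement for a candidate precursor.

    True iff the structure contains exactly one hairpin loop (hence no
    multiloop) and the tag lies entirely on one side of that loop, i.e. on a
    single arm of the stem.  Returns (ok, arm) with arm in {"5p", "3p", "none"}.
    """
    tag = transcribe(tag.upper())
    pos = fold_result.seq.find(tag)
    if pos < 0:
        raise ValueError("tag not found in folded sequence")
    pairs = fold_result.pairs()
    if not pairs:
        return False, "none"
    paired_right = {i: j for i, j in pairs}
    # hairpin-closing pairs: no other pair nested inside
    closing = [(i, j) for i, j in pairs
               if not any(i < k < l < j for k, l in pairs if (k, l) != (i, j))]
    if len(closing) != 1:
        return False, "none"
    hi, hj = closing[0]
    start, end = pos, pos + len(tag) - 1
    if end <= hi:
        return True, "5p"
    if start >= hj:
        return True, "3p"
    return False, "none"


# ---------------------------------------------------------------------------
# Reference (exhaustive) routines.  These re-derive energies from first
# principles and never call the dynamic programs above; they exist so that
# folds and duplexes can be verified independently on small instances.
# ---------------------------------------------------------------------------

def structure_energy(seq: str, structure: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Energy of an explicit structure: sum of loop contributions.

    Raises on illegal pairs, hairpin loops < 3 nt, or interior loops above the
    model's cap (such structures are outside the model's structure space).
    """
    seq = _prepare(seq, "sequence")
    arr = encode(seq)
    pairs = parse_dotbracket(structure)
    total = 0.0
    for i, j in pairs:
        if PAIR_TYPE[arr[i], arr[j]] < 0:
            raise ValueError(f"illegal pair {seq[i]}-{seq[j]} at ({i}, {j})")
        children = _direct_children(i, j, pairs)
        if not children:
            size = j - i - 1
            if size < MIN_HAIRPIN:
                raise ValueError("hairpin loop shorter than 3 nt")
            total += model.hairpin(size)
        elif len(children) == 1:
            (k, l), = children
            e = model.loop(k - i - 1, j - l - 1, _pt(arr, i, j), _pt(arr, k, l))
            if e >= INF:
                raise ValueError("interior loop exceeds the model cap")
            total += e
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += model.ml_a + model.ml_b * (1 + len(children)) + model.ml_c * unpaired
    return total


def _direct_children(i: int, j: int, pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    inside = [(k, l) for k, l in pairs if i < k < l < j]
    return [(k, l) for k, l in inside
            if not any(k2 < k < l < l2 for k2, l2 in inside if (k2, l2) != (k, l))]


def enumerate_structures(seq: str) -> Iterator[str]:
    """Yield every legal secondary structure (dot-bracket) of a short sequence.

    Legal pairs only, minimum hairpin loop 3, no pseudoknots.  Intended for
    sequences up to ~20 nt.
    """
    seq = _prepare(seq, "sequence")
    arr = encode(seq)
    n = len(seq)

    def gen(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        # all pair sets on interval [i, j]
        if j - i < MIN_HAIRPIN + 1:
            yield ()
            return
        # position i unpaired
        yield from gen(i + 1, j)
        # position i paired with k
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if PAIR_TYPE[arr[i], arr[k]] < 0:
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield ((i, k),) + inner + outer

    for pairset in gen(0, n - 1):
        db = ["."] * n
        for i, j in pairset:
            db[i], db[j] = "(", ")"
        yield "".join(db)


def min_energy_exhaustive(seq: str, model: EnergyModel = DEFAULT_MODEL) -> tuple[float, str]:
    """Exhaustive-enumeration MFE of a short sequence (reference for fold)."""
    best_e, best_db = 0.0, "." * len(seq)
    for db in enumerate_structures(seq):
        try:
            e = structure_energy(seq, db, model)
        except ValueError:
            continue
        if e < best_e - 1e-12:
            best_e, best_db = e, db
    return best_e, best_db


def enumerate_duplex_energy(a: str, b: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Exhaustive-enumeration duplex MFE (reference for duplex_mfe, <= 12 nt)."""
    a = _prepare(a, "strand a")
    b = _prepare(b, "strand b")
    aa, bb = encode(a), encode(b)
    n, m = len(a), len(b)
    best = 0.0
    positions_a = range(n)
    for size in range(1, min(n, m) + 1):
        for ia in combinations(positions_a, size):
            for jb in combinations(range(m), size):
                js = tuple(reversed(jb))  # antiparallel: j decreasing with i
                if any(PAIR_TYPE[aa[i], bb[j]] < 0 for i, j in zip(ia, js)):
                    continue
                e = 0.0
                ok = True
                for t in range(1, size):
                    l1 = ia[t] - ia[t - 1] - 1
                    l2 = js[t - 1] - js[t] - 1
                    le = model.loop(l1, l2, _pt_duplex(aa, bb, ia[t - 1], js[t - 1]),
                                    _pt_duplex(aa, bb, ia[t], js[t]))
                    if le >= INF:
                        ok = False
                        break
                    e += le
                if ok and e < best:
                    best = e
    return best
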