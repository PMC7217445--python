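"""Two-level choice-experiment designs: full and fractional factorials,
orthogonality diagnostics, blocking, opt-out augmentation and the
Johnson-Orme minimum sample size rule.

All designs are effect coded: every attribute has exactly two levels,
written +1 (the "high" label) and -1 (the "low" label).  Fractions are
regular 2^(k-p) designs built from minimum-aberration generator tables,
so their alias structure is fully described by a defining relation and
the achieved resolution can be computed exactly by enumerating words.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InfeasibleDesignError, InvalidInputError

__all__ = [
    "Attribute",
    "Profile",
    "DesignPlan",
    "OrthogonalityReport",
    "full_factorial",
    "fractional_factorial",
    "check_orthogonality",
    "assign_blocks",
    "add_opt_out",
    "min_sample_size",
]


@dataclass(frozen=True)
class Attribute:
    """A binary, effect-coded trait.

    ``high_label`` is the level coded +1 and ``low_label`` the level
    coded -1 (e.g. body size: large = +1, small = -1).
    """

    name: str
    description: str = ""
    high_label: str = "high"
    low_label: str = "low"

    def __post_init__(self):
        if not self.name or not str(self.name).isidentifier():
            raise InvalidInputError(
                f"attribute name must be a non-empty identifier, got {self.name!r}"
            )


@dataclass(frozen=True)
class Profile:
    """One hypothetical animal: a vector of effect codes, one per attribute."""

    profile_id: int
    codes: tuple

    def __post_init__(self):
        if any(c not in (-1, 1) for c in self.codes):
            raise InvalidInputError(f"profile codes must be +1/-1, got {self.codes}")


def _check_attributes(attributes):
    if not attributes:
        raise InvalidInputError("attribute list is empty")
    names = [a.name for a in attributes]
    if len(set(names)) != len(names):
        raise InvalidInputError(f"attribute names are not unique: {names}")
    return names


def _profiles_to_matrix(profiles):
    if len(profiles) < 1:
        raise InvalidInputError("need at least one profile")
    lengths = {len(p.codes) for p in profiles}
    if len(lengths) != 1:
        raise InvalidInputError(f"ragged code vectors: lengths {sorted(lengths)}")
    return np.array([p.codes for p in profiles], dtype=int)


def full_factorial(attributes):
    """All 2^k effect-coded profiles, in lexicographic order (+1 before -1)."""
    _check_attributes(attributes)
    k = len(attributes)
    rows = itertools.product((1, -1), repeat=k)
    return [Profile(profile_id=i, codes=codes) for i, codes in enumerate(rows)]


# Minimum-aberration generators for regular 2^(k-p) fractions, indexed by
# (k, p).  Words are over the q = k - p basic factors "ABCD..."; the j-th
# word defines added factor q + j.  Standard catalogue values.
_MA_GENERATORS = {
    (3, 1): ["AB"],
    (4, 1): ["ABC"],
    (5, 1): ["ABCD"],
    (5, 2): ["AB", "AC"],
    (6, 1): ["ABCDE"],
    (6, 2): ["ABC", "BCD"],
    (6, 3): ["AB", "AC", "BC"],
    (7, 1): ["ABCDEF"],
    (7, 2): ["ABCD", "ABDE"],
    (7, 3): ["ABC", "ABD", "ACD"],
    (7, 4): ["AB", "AC", "BC", "ABC"],
    (8, 1): ["ABCDEFG"],
    (8, 2): ["ABCD", "ABEF"],
    (8, 3): ["ABC", "ABD", "BCDE"],
    (8, 4): ["BCD", "ACD", "ABC", "ABD"],
    (9, 4): ["BCDE", "ACDE", "ABDE", "ABCE"],
}


def _word_to_set(word):
    return frozenset(ord(ch) - ord("A") for ch in word)


def _defining_relation(k, p, generator_words):
    """All 2^p - 1 nonempty words of the defining contrast subgroup,
    as frozensets of factor indices (added factor j is index q + j)."""
    q = k - p
    full_words = []
    for j, word in enumerate(generator_words):
        full_words.append(_word_to_set(word) | {q + j})
    relation = []
    for r in range(1, p + 1):
        for combo in itertools.combinations(full_words, r):
            w = frozenset()
            for s in combo:
                w = w.symmetric_difference(s)
            relation.append(w)
    return relation


def fractional_factorial(attributes, n_runs, min_resolution=3):
    """A regular 2^(k-p) fraction with n_runs profiles and resolution at
    least ``min_resolution``, from minimum-aberration generator tables.

    When ``n_runs == 2^k`` the fraction is the full factorial.  Raises
    :class:`InfeasibleDesignError` (naming the best achievable
    resolution) when the tabulated design falls short of the request.
    """
    _check_attributes(attributes)
    k = len(attributes)
    if n_runs < 2 or (n_runs & (n_runs - 1)) != 0:
        raise InvalidInputError(f"n_runs must be a power of 2, got {n_runs}")
    if n_runs > 2 ** k:
        raise InvalidInputError(f"n_runs={n_runs} exceeds 2^{k} profiles")
    if n_runs == 2 ** k:
        return full_factorial(attributes)

    q = int(math.log2(n_runs))
    p = k - q
    if (k, p) not in _MA_GENERATORS:
        raise InfeasibleDesignError(
            f"no generator table entry for a 2^({k}-{p}) design at {n_runs} runs"
        )
    words = _MA_GENERATORS[(k, p)]
    relation = _defining_relation(k, p, words)
    resolution = min(len(w) for w in relation)
    if resolution < min_resolution:
        raise InfeasibleDesignError(
            f"requested resolution {min_resolution} but the best regular "
            f"2^({k}-{p}) fraction at {n_runs} runs achieves resolution "
            f"{resolution}",
            best_resolution=resolution,
        )

    # basic factors: full factorial on q columns; added factors: products.
    basic = np.array(list(itertools.product((1, -1), repeat=q)), dtype=int)
    cols = [basic[:, j] for j in range(q)]
    for j, word in enumerate(words):
        prod = np.ones(n_runs, dtype=int)
        for idx in _word_to_set(word):
            prod = prod * basic[:, idx]
        cols.append(prod)
    mat = np.column_stack(cols)
    # deterministic ordering: lexicographic with +1 first
    order = sorted(range(n_runs), key=lambda r: tuple(-mat[r, j] for j in range(k)))
    mat = mat[order]
    return [Profile(profile_id=i, codes=tuple(int(c) for c in mat[i])) for i in range(n_runs)]


@dataclass
class OrthogonalityReport:
    """Balance and orthogonality diagnostics for a two-level design."""

    n_runs: int
    column_sums: np.ndarray
    cross_products: np.ndarray
    violations: list
    resolution: int | None

    @property
    def is_orthogonal_array(self):
        return not self.violations


def _achieved_resolution(mat):
    """Minimum word length of the defining relation of a regular fraction,
    found by enumerating constant interaction columns; None when no
    subset of columns multiplies to a constant (e.g. a full factorial)."""
    n, k = mat.shape
    if k > 16:  # enumeration guard; designs here are small
        return None
    best = None
    for r in range(1, k + 1):
        if best is not None:
            break
        for combo in itertools.combinations(range(k), r):
            prod = mat[:, combo].prod(axis=1)
            if abs(int(prod.sum())) == n:
                best = r
                break
    return best


def check_orthogonality(profiles):
    """Column balance, pairwise inner products, and achieved resolution.

    For an orthogonal array of n runs every column sums to 0 and the
    cross-product matrix equals n times the identity; any departure is
    listed in ``violations``.
    """
    if len(profiles) < 2:
        raise InvalidInputError("need at least two profiles")
    mat = _profiles_to_matrix(profiles)
    n, k = mat.shape
    sums = mat.sum(axis=0)
    xtx = mat.T @ mat
    violations = []
    for j in range(k):
        if sums[j] != 0:
            violations.append(f"column {j} is unbalanced (sum {int(sums[j])})")
    for i in range(k):
        for j in range(i + 1, k):
            if xtx[i, j] != 0:
                violations.append(
                    f"columns {i} and {j} are not orthogonal "
                    f"(inner product {int(xtx[i, j])})"
                )
    return OrthogonalityReport(
        n_runs=n,
        column_sums=sums,
        cross_products=xtx,
        violations=violations,
        resolution=_achieved_resolution(mat),
    )


@dataclass
class DesignPlan:
    """A blocked choice-experiment design.

    Each block is one choice situation offering its profiles as the
    designed alternatives; ``opt_out[b]`` records whether block b also
    carries a "none of these" option (which bears no attribute codes and
    never enters the design algebra).
    """

    attributes: list
    profiles: list
    n_blocks: int
    block_assignment: dict  # profile_id -> block index (0-based)
    opt_out: list = field(default_factory=list)
    resolution: int | None = None
    positions: dict = field(default_factory=dict)  # profile_id -> within-block order

    def __post_init__(self):
        if not self.opt_out:
            self.opt_out = [False] * self.n_blocks
        ids = [p.profile_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("duplicate profile_id in plan")
        if set(self.block_assignment) != set(ids):
            raise InvalidInputError("block assignment does not cover all profiles")
        sizes = self.block_sizes()
        if len(set(sizes)) > 1:
            raise InvalidInputError(f"blocks have unequal sizes: {sizes}")
        if not self.positions:
            self.positions = {pid: i for i, pid in enumerate(ids)}

    def block_sizes(self):
        counts = [0] * self.n_blocks
        for b in self.block_assignment.values():
            counts[b] += 1
        return counts

    def block_profiles(self, b):
        profs = [p for p in self.profiles if self.block_assignment[p.profile_id] == b]
        return sorted(profs, key=lambda p: self.positions[p.profile_id])

    def to_frame(self):
        """Long-format table: one row per alternative (designed or opt-out)."""
        names = [a.name for a in self.attributes]
        rows = []
        for b in range(self.n_blocks):
            for alt, prof in enumerate(self.block_profiles(b), start=1):
                row = {"block": b + 1, "alternative": alt, "is_opt_out": 0}
                row.update(dict(zip(names, prof.codes)))
                rows.append(row)
            if self.opt_out[b]:
                row = {
                    "block": b + 1,
                    "alternative": len(self.block_profiles(b)) + 1,
                    "is_opt_out": 1,
                }
                row.update({nm: 0 for nm in names})
                rows.append(row)
        return pd.DataFrame(rows, columns=["block", "alternative", *names, "is_opt_out"])

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "attributes": [
                {
                    "name": a.name,
                    "description": a.description,
                    "high_label": a.high_label,
                    "low_label": a.low_label,
                }
                for a in self.attributes
            ],
            "n_blocks": self.n_blocks,
            "resolution": self.resolution,
            "opt_out": list(self.opt_out),
            "profiles": [
                {
                    "profile_id": p.profile_id,
                    "codes": list(p.codes),
                    "block": self.block_assignment[p.profile_id],
                    "position": self.positions[p.profile_id],
                }
                for p in self.profiles
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path_or_text):
        try:
            payload = json.loads(path_or_text)
        except (json.JSONDecodeError, TypeError):
            with open(path_or_text) as fh:
                payload = json.load(fh)
        attributes = [Attribute(**a) for a in payload["attributes"]]
        profiles = [
            Profile(profile_id=p["profile_id"], codes=tuple(p["codes"]))
            for p in payload["profiles"]
        ]
        assignment = {p["profile_id"]: p["block"] for p in payload["profiles"]}
        positions = {
            p["profile_id"]: p.get("position", i)
            for i, p in enumerate(payload["profiles"])
        }
        return cls(
            attributes=attributes,
            profiles=profiles,
            n_blocks=payload["n_blocks"],
            block_assignment=assignment,
            opt_out=list(payload["opt_out"]),
            resolution=payload["resolution"],
            positions=positions,
        )


def _balance_score(mat, assignment, n_blocks):
    """Sum over blocks and columns of |within-block column sum|; 0 is
    perfectly level-balanced within every block."""
    score = 0
    for b in range(n_blocks):
        sub = mat[assignment == b]
        score += int(np.abs(sub.sum(axis=0)).sum())
    return score


def _centered_min_singular(mat, perm, n_blocks, size):
    """Smallest singular value of the within-situation-centered design
    matrix (position dummies above the reference + attribute codes) for a
    candidate presentation order.  Zero means some utility contrast is
    confounded with the blocking and unidentifiable from choices."""
    n, k = mat.shape
    rows = mat[perm]
    asc = np.zeros((n, size - 1))
    pos = np.tile(np.arange(size), n_blocks)
    for j in range(1, size):
        asc[pos == j, j - 1] = 1.0
    design = np.hstack([asc, rows])
    blocks = np.repeat(np.arange(n_blocks), size)
    for b in range(n_blocks):
        m = blocks == b
        design[m] -= design[m].mean(axis=0)
    return float(np.linalg.svd(design, compute_uv=False)[-1])


def assign_blocks(profiles, n_blocks, seed, attributes=None, n_candidates=2000):
    """Partition profiles into equal blocks by seeded balanced randomization.

    Draws ``n_candidates`` random equal partitions (which also fix the
    within-block presentation order) from a generator seeded with
    ``seed`` and keeps the most level-balanced one among those whose
    centered design matrix keeps every utility contrast identifiable
    (ties broken by draw order), so the assignment is reproducible from
    the seed.
    """
    mat = _profiles_to_matrix(profiles)
    n, k = mat.shape
    if n_blocks < 1 or n % n_blocks != 0:
        raise InvalidInputError(f"{n_blocks} blocks do not divide {n} profiles evenly")
    if attributes is None:
        attributes = [Attribute(name=f"x{j + 1}") for j in range(k)]
    if len(attributes) != k:
        raise InvalidInputError("attribute list does not match profile length")

    size = n // n_blocks
    base = np.repeat(np.arange(n_blocks), size)
    rng = np.random.default_rng(seed)
    best = None  # minimize (unidentifiable, balance score, -conditioning)
    best_perm = None
    for _ in range(max(1, n_candidates)):
        perm = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        assignment[perm] = base
        score = _balance_score(mat, assignment, n_blocks)
        smin = 1.0 if size < 2 else _centered_min_singular(mat, perm, n_blocks, size)
        key = (smin <= 1e-8, score, -smin)
        if best is None or key < best:
            best, best_perm, best_assign = key, perm, assignment
    ids = [p.profile_id for p in profiles]
    positions = np.empty(n, dtype=int)
    positions[best_perm] = np.tile(np.arange(size), n_blocks)
    return DesignPlan(
        attributes=list(attributes),
        profiles=list(profiles),
        n_blocks=n_blocks,
        block_assignment={pid: int(b) for pid, b in zip(ids, best_assign)},
        resolution=_achieved_resolution(mat),
        positions={pid: int(p) for pid, p in zip(ids, positions)},
    )


def add_opt_out(plan):
    """Return a plan whose every block offers an opt-out alternative.

    Idempotent: blocks already flagged keep a single opt-out.
    """
    if plan.n_blocks < 1:
        raise InvalidInputError("plan has no blocks")
    return replace(plan, opt_out=[True] * plan.n_blocks)


@dataclass(frozen=True)
class SampleSizeInputs:
    """Inputs to the Johnson-Orme rule N > 500 c / (t a)."""

    c: int  # highest number of levels of any attribute
    t: int  # choice tasks per respondent
    a: int  # alternatives per task

    def __post_init__(self):
        for nm in ("c", "t", "a"):
            v = getattr(self, nm)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise InvalidInputError(f"{nm} must be a positive integer, got {v!r}")
        if self.c < 2:
            raise InvalidInputError("attributes have at least 2 levels (c >= 2)")


def min_sample_size(inputs=None, *, c=None, t=None, a=None):
    """Minimum respondent count from the rule-of-thumb N > 500 c / (t a).

    Returns the smallest integer exceeding the bound, except that when
    the bound itself is an integer it is returned as-is (the convention
    under which c=2, t=1, a=4 gives 250).
    """
    if inputs is None:
        inputs = SampleSizeInputs(c=c, t=t, a=a)
    bound = 500 * inputs.c / (inputs.t * inputs.a)
    return int(math.ceil(bound))
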