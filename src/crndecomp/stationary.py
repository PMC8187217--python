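"""Stationary distributions: master-equation solves, generalized balance,
product-form functions, factorization and summability.

Product-form functions are handled through their successive ratios
ρ(x) = f(x)/f(x−1) with f(0) = 1, accumulated in log space — factorials
underflow long before the distributions they normalize become negligible.

The direct solver computes the null space of the generator restricted to a
finite closed component; it is the oracle everything else is compared
against.  Generalized balance is the structural notion that a partition of
the reactions into (L, R) tuples balances the master equation term by term;
any valid generalized-balance certificate implies stationarity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import logsumexp

from .config import DEFAULT, Settings
from .errors import ClosureError, ValidationError
from .kinetics import KineticsSpec, RateLaw, mass_action
from .network import ReactionNetwork
from .statespace import IrreducibleComponent, StochasticSystem

__all__ = [
    "ProductFormFunction",
    "StationaryDistribution",
    "BalancePartition",
    "solve_master_direct",
    "explicit_from_product",
    "check_generalized_balance",
    "master_equation_residual",
    "poisson_product_form",
    "motif_product_form",
    "factorize_product_form",
    "factorize_components",
    "FactorizationResult",
    "proportionality_match",
    "ratio_test_summability",
    "total_variation",
]


_MA = mass_action()


class ProductFormFunction:
    """A per-species factor f: Z≥0 → R>0, stored via successive ratios.

    ``ratio_fn(x)`` must return ρ(x) = f(x)/f(x−1) > 0 for x ≥ 1; log f is
    the cumulative sum of log ratios (f(0) = 1).  When the function only
    exists on a finite range (e.g. extracted from a factorized explicit
    distribution) set ``finite_range`` and evaluation beyond it raises.
    """

    def __init__(
        self,
        ratio_fn: Callable[[int], float],
        tag: str = "custom",
        meta: Optional[dict] = None,
        finite_range: Optional[int] = None,
    ):
        self._ratio_fn = ratio_fn
        self.tag = tag
        self.meta = dict(meta or {})
        self.finite_range = finite_range
        self._log = [0.0]

    # -- constructors ------------------------------------------------------
    @classmethod
    def poisson(cls, c: float, theta: RateLaw | None = None) -> "ProductFormFunction":
        """Poisson-type factor f(x) = c^x / ∏_{l≤x} θ(l) (θ(x)=x gives c^x/x!)."""
        if not c > 0:
            raise ValidationError("poisson rate must be positive")
        theta = theta or _MA
        return cls(lambda x: c / theta(x), tag="poisson", meta={"c": c, "theta": theta})

    @classmethod
    def from_log_table(cls, log_values: Sequence[float]) -> "ProductFormFunction":
        """Finite f from log f(0..n); gauge-shifted so f(0) = 1."""
        base = log_values[0]
        logs = [v - base for v in log_values]
        ratios = [math.exp(logs[x] - logs[x - 1]) for x in range(1, len(logs))]
        return cls(
            lambda x: ratios[x - 1],
            tag="table",
            finite_range=len(logs) - 1,
        )

    # -- evaluation --------------------------------------------------------
    def ratio(self, x: int) -> float:
        if x < 1:
            raise ValidationError("ratios are defined for x >= 1")
        if self.finite_range is not None and x > self.finite_range:
            raise ValidationError(f"function only defined up to {self.finite_range}")
        value = self._ratio_fn(x)
        if not (value > 0) or not math.isfinite(value):
            raise ValidationError(f"nonpositive ratio {value} at x={x}")
        return value

    def log_f(self, x: int) -> float:
        if x < 0:
            raise ValidationError("f is defined on nonnegative integers")
        while len(self._log) <= x:
            self._log.append(self._log[-1] + math.log(self.ratio(len(self._log))))
        return self._log[x]

    def f(self, x: int) -> float:
        return math.exp(self.log_f(x))

    def tilted(self, d: float, weight: float = 1.0) -> "ProductFormFunction":
        """Exponential tilt f(x) → d^(w·x) f(x) (the conservation-law free constant)."""
        if not d > 0:
            raise ValidationError("tilt must be positive")
        factor = d**weight
        meta = dict(self.meta)
        meta["tilt"] = meta.get("tilt", 1.0) * factor
        return ProductFormFunction(
            lambda x: self._ratio_fn(x) * factor,
            tag=self.tag,
            meta=meta,
            finite_range=self.finite_range,
        )

    def tail_ratio_estimate(self) -> Optional[float]:
        """Estimated limit of ρ(x) as x → ∞ for the ratio test; None if unknown."""
        if self.finite_range is not None:
            return None
        try:
            far, farther = self._ratio_fn(10**6), self._ratio_fn(10**7)
        except Exception:
            return None
        if not (math.isfinite(far) and math.isfinite(farther)):
            return None
        if abs(far - farther) > 1e-3 * (1.0 + abs(farther)):
            return None
        return farther

    def __repr__(self) -> str:
        return f"ProductFormFunction(tag={self.tag!r}, meta={self.meta!r})"


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass
class StationaryDistribution:
    """A stationary distribution on an irreducible component.

    Either explicit (a normalized probability vector aligned with
    ``component.states``) or product form (one factor per species plus the
    log normalizing constant over the component) — product-form results also
    carry the explicit vector over the (finite or truncated) component.
    """

    component: IrreducibleComponent
    probs: np.ndarray
    form: str = "explicit"  # "explicit" | "product"
    functions: Optional[dict[str, ProductFormFunction]] = None
    log_z: Optional[float] = None
    residual: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != len(self.component.states):
            raise ValidationError("probability vector does not match the component")
        if np.any(self.probs < -1e-12):
            raise ValidationError("negative probability")
        total = self.probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"probabilities sum to {total}, not 1")
        self.probs = np.clip(self.probs, 0.0, None)
        self.probs /= self.probs.sum()

    def prob(self, state: Sequence[int]) -> float:
        i = self.component.index().get(tuple(state))
        return 0.0 if i is None else float(self.probs[i])

    def mean(self) -> np.ndarray:
        states = np.array(self.component.states, dtype=float)
        return states.T @ self.probs

    def to_json(self) -> dict:
        data = {
            "species": list(self.component.species),
            "states": [list(state) for state in self.component.states],
            "probs": self.probs.tolist(),
            "form": self.form,
            "residual": self.residual,
        }
        if self.log_z is not None:
            data["log_z"] = self.log_z
        if self.functions is not None:
            # per-species successive-ratio tables over the component's range
            tables = {}
            for i, s in enumerate(self.component.species):
                top = max(state[i] for state in self.component.states)
                tables[s] = [self.functions[s].ratio(x) for x in range(1, top + 1)]
            data["ratio_tables"] = tables
        return data

    def to_tsv(self) -> str:
        lines = ["\t".join(list(self.component.species) + ["prob"])]
        for state, value in zip(self.component.states, self.probs):
            lines.append("\t".join(str(v) for v in state) + f"\t{value!r}")
        return "\n".join(lines) + "\n"


def total_variation(d1: StationaryDistribution, d2: StationaryDistribution) -> float:
    """TV distance, aligned on the union of the two supports."""
    states = set(d1.component.states) | set(d2.component.states)
    return 0.5 * sum(abs(d1.prob(s) - d2.prob(s)) for s in states)


def explicit_from_product(
    component: IrreducibleComponent,
    functions: Mapping[str, ProductFormFunction],
) -> StationaryDistribution:
    """Normalize π(x) ∝ ∏_i f_i(x_i) over the component (log-space)."""
    species = component.species
    missing = [s for s in species if s not in functions]
    if missing:
        raise ValidationError(f"no product-form function for species {missing}")
    fns = [functions[s] for s in species]
    logs = np.array(
        [sum(fn.log_f(v) for fn, v in zip(fns, state)) for state in component.states]
    )
    log_z = float(logsumexp(logs))
    return StationaryDistribution(
        component=component,
        probs=np.exp(logs - log_z),
        form="product",
        functions=dict(functions),
        log_z=log_z,
    )


# ---------------------------------------------------------------------------
# direct master-equation solve
# ---------------------------------------------------------------------------

def _generator(
    network: ReactionNetwork, kinetics: KineticsSpec | None, component: IrreducibleComponent
) -> sp.csr_matrix:
    system = StochasticSystem(network, kinetics)
    index = component.index()
    rows, cols, vals = [], [], []
    for i, state in enumerate(component.states):
        out_rate = 0.0
        for target, rate in system.successors(state).items():
            j = index.get(target)
            if j is None:
                if component.truncated:
                    continue  # reflected at the exploration boundary
                raise ClosureError(
                    f"component is not closed: {state} -> {target}"
                )
            rows.append(i)
            cols.append(j)
            vals.append(rate)
            out_rate += rate
        rows.append(i)
        cols.append(i)
        vals.append(-out_rate)
    n = len(component.states)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def solve_master_direct(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    component: IrreducibleComponent,
    *,
    settings: Settings = DEFAULT,
    allow_truncated: bool = False,
) -> StationaryDistribution:
    """Solve πQ = 0, Σπ = 1 on a finite closed component.

    One row of the transposed generator is replaced by the normalization
    constraint; dense LU below ``settings.dense_solver_limit`` states, sparse
    LU above.  The max-norm residual ‖πQ‖∞ is recorded.  A finite closed
    communicating class has a unique stationary distribution, so a
    non-one-dimensional null space (detected as a singular solve or a
    negative solution) signals a bug and raises.

    ``allow_truncated=True`` solves the chain reflected at the exploration
    boundary (jumps out of the bound dropped) — the stationary distribution
    of the truncation, close to the true one only when the suppressed tail
    mass is negligible.
    """
    if not component.closed:
        raise ClosureError("direct solve requires a closed component")
    if component.truncated and not allow_truncated:
        raise ClosureError("direct solve requires an untruncated component")
    n = len(component.states)
    if n == 0:
        raise ValidationError("empty component")
    if n == 1:
        return StationaryDistribution(
            component=component, probs=np.array([1.0]), residual=0.0
        )
    generator = _generator(network, kinetics, component)
    transposed = generator.T.tocsr()
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    if n <= settings.dense_solver_limit:
        matrix = transposed.toarray()
        matrix[-1, :] = 1.0
        try:
            pi = np.linalg.solve(matrix, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "singular master-equation system (null space dimension != 1?)"
            ) from exc
    else:
        matrix = transposed.tolil()
        matrix[-1, :] = 1.0
        pi = spla.spsolve(matrix.tocsr(), rhs)
    top = float(np.max(np.abs(pi)))
    if float(np.min(pi)) < -1e-8 * top:
        raise ValidationError(
            "negative stationary probabilities: null space dimension != 1"
        )
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    residual = float(np.max(np.abs(transposed @ pi)))
    return StationaryDistribution(component=component, probs=pi, residual=residual)


# ---------------------------------------------------------------------------
# generalized balance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BalancePartition:
    """A set of tuples (L_i, R_i) of reaction-index subsets whose L's and R's
    each partition the reaction set."""

    tuples: tuple[tuple[frozenset, frozenset], ...]

    def validate(self, network: ReactionNetwork) -> None:
        all_idx = set(range(len(network.reactions)))
        for side in (0, 1):
            seen: set[int] = set()
            for tup in self.tuples:
                part = tup[side]
                if part & seen:
                    raise ValidationError("balance partition subsets overlap")
                seen |= part
            if seen != all_idx:
                raise ValidationError("balance partition does not cover the reactions")

    # -- named constructors (the classical special cases) -------------------
    @classmethod
    def trivial(cls, network: ReactionNetwork) -> "BalancePartition":
        """One tuple (R, R): plain stationarity (the full master equation)."""
        everything = frozenset(range(len(network.reactions)))
        return cls(tuples=((everything, everything),))

    @classmethod
    def per_part(
        cls, network: ReactionNetwork, parts: Sequence[Iterable[int]]
    ) -> "BalancePartition":
        """{(R_j, R_j)}_j for a reaction-disjoint split into parts."""
        return cls(
            tuples=tuple((frozenset(p), frozenset(p)) for p in parts)
        )

    @classmethod
    def reaction_balanced(cls, network: ReactionNetwork) -> "BalancePartition":
        """Pairs ({ν→ν'}, {ν'→ν}); requires a reversible network."""
        key_index = {r.key: i for i, r in enumerate(network.reactions)}
        tuples = []
        for i, r in enumerate(network.reactions):
            j = key_index.get(r.reversed_key())
            if j is None:
                raise ValidationError(
                    "reaction-balanced partition requires a reversible network"
                )
            tuples.append((frozenset([i]), frozenset([j])))
        return cls(tuples=tuple(tuples))

    @classmethod
    def complex_indexed(cls, network: ReactionNetwork) -> "BalancePartition":
        """Per complex C: inflow reactions (ν' = C) against outflow (ν = C)."""
        tuples = []
        for cplx in sorted(network.complexes, key=lambda c: c.format()):
            into = frozenset(
                i for i, r in enumerate(network.reactions) if r.product == cplx
            )
            out = frozenset(
                i for i, r in enumerate(network.reactions) if r.reactant == cplx
            )
            tuples.append((into, out))
        return cls(tuples=tuple(tuples))

    @classmethod
    def reaction_vector_balanced(cls, network: ReactionNetwork) -> "BalancePartition":
        """Per jump vector a: reactions with ν−ν' = a against those with ν−ν' = −a."""
        by_vec: dict[tuple, set] = {}
        for i, r in enumerate(network.reactions):
            vec = tuple(-v for v in r.jump(network.species))
            by_vec.setdefault(vec, set()).add(i)
        tuples = []
        for vec in sorted(by_vec):
            neg = tuple(-v for v in vec)
            tuples.append(
                (frozenset(by_vec[vec]), frozenset(by_vec.get(neg, set())))
            )
        return cls(tuples=tuple(tuples))


def check_generalized_balance(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    dist: StationaryDistribution,
    partition: BalancePartition,
    *,
    settings: Settings = DEFAULT,
) -> tuple[bool, float]:
    """Verify the balance equations of *partition* for *dist* on its component.

    For every tuple (L, R) and every state x:
    Σ_{ν→ν'∈L} π(x+ν−ν') λ(x+ν−ν') = π(x) Σ_{ν→ν'∈R} λ(x),
    with π vanishing outside the component.  Returns (ok, max residual);
    a pass certifies stationarity (any generalized-balance partition does).
    """
    partition.validate(network)
    system = StochasticSystem(network, kinetics)
    component = dist.component
    species = network.species
    jumps = [r.jump(species) for r in network.reactions]
    max_residual = 0.0
    scale = 1.0
    for left, right in partition.tuples:
        for state in component.states:
            rhs_rate = sum(system.propensity(i, state) for i in right)
            rhs = dist.prob(state) * rhs_rate
            lhs = 0.0
            for i in left:
                shifted = tuple(v - j for v, j in zip(state, jumps[i]))
                if any(v < 0 for v in shifted):
                    continue
                p = dist.prob(shifted)
                if p:
                    lhs += p * system.propensity(i, shifted)
            max_residual = max(max_residual, abs(lhs - rhs))
            scale = max(scale, abs(rhs), abs(lhs))
    ok = max_residual <= settings.balance_residual * scale
    return ok, max_residual


def master_equation_residual(
    network: ReactionNetwork,
    kinetics: KineticsSpec | None,
    dist: StationaryDistribution,
) -> float:
    """Max-norm residual of the full master equation for *dist*."""
    _, residual = check_generalized_balance(
        network, kinetics, dist, BalancePartition.trivial(network)
    )
    return residual


# ---------------------------------------------------------------------------
# closed-form product families
# ---------------------------------------------------------------------------

def poisson_product_form(
    c: Sequence[float],
    component: IrreducibleComponent,
    kinetics: KineticsSpec | None = None,
) -> StationaryDistribution:
    """Poisson-type product form π(x) = M_Γ c^x/x! at a point of complex balance.

    With general kinetics the factorial generalizes to ∏_{l≤x} θ_i(l).
    """
    kinetics = kinetics or KineticsSpec()
    functions = {
        s: ProductFormFunction.poisson(ci, kinetics.theta(s))
        for s, ci in zip(component.species, c)
    }
    return explicit_from_product(component, functions)


def motif_product_form(
    kappa1: float,
    kappa2: float,
    kappa3: float,
    kappa4: float,
    theta1: RateLaw | None = None,
    theta2: RateLaw | None = None,
    d: float = 1.0,
) -> tuple[ProductFormFunction, ProductFormFunction]:
    """Product-form factors of the motif S1 ⇌ S2, 2S1 ⇌ S1+S2.

    Rates: κ1 (S1→S2), κ2 (S2→S1), κ3 (2S1→S1+S2), κ4 (S1+S2→2S1).  The
    factors on an irreducible component {x1 + x2 = N} are

        f1(x) = d^x / ∏_{l≤x} θ1(l) · ∏_{l≤x} (κ2 + κ4 θ1(l−1)) / (κ1 + κ3 θ1(l−1)),
        f2(x) = d^x / ∏_{l≤x} θ2(l),

    with d > 0 a free constant (the conservation law x1+x2 makes all choices
    of d give the same normalized distribution).  Mass-action θ(x) = x
    recovers the classical form f1(x) = (1/x!) ∏ (κ2+κ4(l−1))/(κ1+κ3(l−1)).
    """
    for value in (kappa1, kappa2, kappa3, kappa4, d):
        if not value > 0:
            raise ValidationError("motif rates and d must be positive")
    theta1 = theta1 or _MA
    theta2 = theta2 or _MA

    def ratio1(x: int) -> float:
        prev = theta1(x - 1)
        return d * (kappa2 + kappa4 * prev) / (theta1(x) * (kappa1 + kappa3 * prev))

    f1 = ProductFormFunction(
        ratio1,
        tag="motif",
        meta={"kappas": (kappa1, kappa2, kappa3, kappa4), "d": d},
    )
    f2 = ProductFormFunction(
        lambda x: d / theta2(x), tag="poisson", meta={"c": d, "theta": theta2}
    )
    return f1, f2


# ---------------------------------------------------------------------------
# factorization of explicit distributions
# ---------------------------------------------------------------------------

@dataclass
class FactorizationResult:
    """Least-squares product-form fit of log π over one or more components.

    ``tables[j]`` maps each observed projected tuple of group j to its fitted
    log-factor, gauge-fixed to 0 at the smallest observed tuple; the
    per-component constants absorb the normalization.  ``ok`` is the
    product-form verdict (max log-residual below the configured threshold).
    """

    grouping: tuple[tuple[str, ...], ...]
    tables: list[dict[tuple, float]]
    constants: list[float]
    max_residual: float
    ok: bool

    def function_for(self, species_name: str) -> ProductFormFunction:
        """Singleton-group table as a ProductFormFunction (contiguous range only)."""
        for group, table in zip(self.grouping, self.tables):
            if group == (species_name,):
                xs = sorted(v[0] for v in table)
                if xs != list(range(xs[0], xs[-1] + 1)):
                    raise ValidationError(
                        f"support of {species_name} is not contiguous"
                    )
                if xs[0] != 0:
                    raise ValidationError(
                        f"support of {species_name} does not start at 0"
                    )
                return ProductFormFunction.from_log_table(
                    [table[(x,)] for x in xs]
                )
        raise ValidationError(f"{species_name} is not a singleton group")


def factorize_components(
    state_sets: Sequence[Sequence[tuple]],
    log_weights: Sequence[Sequence[float]],
    species: Sequence[str],
    grouping: Sequence[Sequence[str]] | None = None,
    *,
    settings: Settings = DEFAULT,
) -> FactorizationResult:
    """Joint least-squares fit log π = Σ_j g_j(x_group) + const_k over several
    components sharing the same group functions (one constant per component)."""
    if grouping is None:
        grouping = [(s,) for s in species]
    grouping = tuple(tuple(g) for g in grouping)
    flat = [s for g in grouping for s in g]
    if sorted(flat) != sorted(species):
        raise ValidationError("grouping must partition the species")
    group_idx = [[list(species).index(s) for s in g] for g in grouping]

    # collect observed projections
    value_index: list[dict[tuple, int]] = []
    columns = 0
    refs: list[tuple] = []
    for idx in group_idx:
        observed = sorted(
            {tuple(state[i] for i in idx) for states in state_sets for state in states}
        )
        refs.append(observed[0])
        mapping = {}
        for v in observed[1:]:
            mapping[v] = columns
            columns += 1
        value_index.append(mapping)
    n_comp = len(state_sets)
    n_rows = sum(len(states) for states in state_sets)
    design = np.zeros((n_rows, columns + n_comp))
    target = np.zeros(n_rows)
    row = 0
    for k, (states, logs) in enumerate(zip(state_sets, log_weights)):
        for state, logw in zip(states, logs):
            for j, idx in enumerate(group_idx):
                v = tuple(state[i] for i in idx)
                col = value_index[j].get(v)
                if col is not None:
                    design[row, col] = 1.0
            design[row, columns + k] = 1.0
            target[row] = logw
            row += 1
    solution, *_ = np.linalg.lstsq(design, target, rcond=None)
    residuals = target - design @ solution
    tables = []
    for j, mapping in enumerate(value_index):
        table = {refs[j]: 0.0}
        for v, col in mapping.items():
            table[v] = float(solution[col])
        tables.append(table)
    max_residual = float(np.max(np.abs(residuals))) if n_rows else 0.0
    return FactorizationResult(
        grouping=grouping,
        tables=tables,
        constants=[float(solution[columns + k]) for k in range(n_comp)],
        max_residual=max_residual,
        ok=max_residual < settings.factorization_residual,
    )


def factorize_product_form(
    dist: StationaryDistribution,
    grouping: Sequence[Sequence[str]] | None = None,
    *,
    settings: Settings = DEFAULT,
) -> Optional[FactorizationResult]:
    """Test whether an explicit distribution factorizes over species groups.

    Singleton groups test the per-species product form; coarser groups test
    block factorizations.  Returns None when no factorization exists at the
    configured residual threshold.  On conservative components factorizations
    are unique only up to exponential tilts along conservation laws, so the
    residual — not the fitted functions — is the decision criterion.
    """
    support = [
        (state, math.log(p))
        for state, p in zip(dist.component.states, dist.probs)
        if p > 0.0
    ]
    result = factorize_components(
        [[s for s, _ in support]],
        [[v for _, v in support]],
        dist.component.species,
        grouping,
        settings=settings,
    )
    return result if result.ok else None


# ---------------------------------------------------------------------------
# proportionality and summability
# ---------------------------------------------------------------------------

def proportionality_match(
    f: ProductFormFunction,
    h: ProductFormFunction,
    domain: Iterable[int],
    *,
    settings: Settings = DEFAULT,
) -> Optional[float]:
    """α > 0 with h = α f on *domain*, or None.

    α is anchored at the smallest domain point and the remaining points are
    checked to relative tolerance in log space (the shared-species
    proportionality hypothesis, per-species constants allowed).
    """
    points = sorted(set(int(x) for x in domain))
    if not points:
        raise ValidationError("empty proportionality domain")
    log_alpha = h.log_f(points[0]) - f.log_f(points[0])
    for x in points[1:]:
        gap = h.log_f(x) - f.log_f(x) - log_alpha
        if abs(gap) > settings.proportionality_rtol * max(
            1.0, abs(h.log_f(x))
        ):
            return None
    return math.exp(log_alpha)


def ratio_test_summability(
    functions: Iterable[ProductFormFunction],
    component: IrreducibleComponent | None = None,
) -> str:
    """``"summable"``, ``"divergent"`` or ``"inconclusive"``.

    A finite (untruncated) component is always summable.  On an infinite
    product of per-species ranges the verdict comes from the limits of the
    successive ratios (the ratio test): all limits < 1 ⇒ summable, any
    limit > 1 ⇒ divergent, limit 1 or no usable closed form ⇒ inconclusive —
    the inconclusive verdict is deliberate, not a failure mode.
    """
    if component is not None and not component.truncated:
        return "summable"
    eps = 1e-6  # ratios drifting toward 1 must land in the inconclusive band
    verdict = "summable"
    for fn in functions:
        limit = fn.tail_ratio_estimate()
        if limit is None:
            verdict = "inconclusive"
            continue
        if limit > 1.0 + eps:
            return "divergent"
        if limit >= 1.0 - eps:
            verdict = "inconclusive"
    return verdict
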