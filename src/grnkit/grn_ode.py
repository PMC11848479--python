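"""Hill-function ODE models built from a signed topology with AND/OR logic.

A topology is a set of :class:`RegulationTerm` (target, regulator, sign).
Each target gene's terms are partitioned into AND-blocks that are combined
by OR: the production of gene *i* is

    b_i + sum over blocks [ v_block * prod over block terms of Hill fraction ]

minus linear degradation ``d_i * g_i``.  Mutant genotypes enter through
activity fractions ``f`` multiplying the regulator concentration inside
every Hill fraction.  Enumerating all partitions of each gene's term set
yields the AND/OR logic variant family.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .data_core import GenotypeSpec

__all__ = [
    "RegulationTerm",
    "ODEModelSpec",
    "ParameterSet",
    "SteadyStateError",
    "ParameterMismatchError",
    "hill_activation",
    "hill_repression",
    "enumerate_logic_variants",
    "set_partitions",
    "build_rhs",
    "steady_state",
    "genotype_panel",
    "late_l1_terms",
    "naive_literature_terms",
    "LATE_L1_GENES",
]

LATE_L1_GENES: tuple[str, ...] = ("elt-1", "egl-18", "ceh-16")

ACTIVATION = "activation"
REPRESSION = "repression"


class SteadyStateError(RuntimeError):
    """ODE integration failed to reach a fixed point; carries the tail state."""

    def __init__(self, message: str, state=None, rates=None):
        super().__init__(message)
        self.state = state
        self.rates = rates


class ParameterMismatchError(KeyError):
    """A model spec requires a parameter the ParameterSet does not define."""


@dataclasses.dataclass(frozen=True)
class RegulationTerm:
    target: str
    regulator: str
    sign: str  # "activation" | "repression"
    self_flag: bool = False

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, REPRESSION):
            raise ValueError(f"sign must be activation/repression, got {self.sign!r}")

    @property
    def k_name(self) -> str:
        role = "self" if self.self_flag else ("act" if self.sign == ACTIVATION else "rep")
        return f"k:{self.regulator}:{role}"

    def label(self) -> str:
        return f"{self.regulator}(self)" if self.self_flag else self.regulator


def _block_v_name(target: str, block: Sequence[RegulationTerm]) -> str:
    return f"v:{target}:" + "+".join(t.label() for t in block)


@dataclasses.dataclass(frozen=True)
class ODEModelSpec:
    """A topology plus an AND/OR logic partition of each gene's terms.

    ``blocks`` maps each target gene to a tuple of AND-blocks (tuples of
    terms); blocks are combined by OR (summation).  ``signed`` switches the
    sign-relaxed mode in which the sign of a block's rate parameter selects
    activation (positive) versus repression (negative) at evaluation time.
    """

    genes: tuple[str, ...]
    blocks: Mapping[str, tuple[tuple[RegulationTerm, ...], ...]]
    variant_id: int = 0
    signed: bool = False

    def __post_init__(self) -> None:
        for gene, blks in self.blocks.items():
            if gene not in self.genes:
                raise ValueError(f"block target {gene!r} not in gene list")
            seen = set()
            for blk in blks:
                for term in blk:
                    if term.target != gene:
                        raise ValueError(f"term {term} filed under target {gene!r}")
                    if term in seen:
                        raise ValueError(f"duplicate term {term}")
                    seen.add(term)

    def terms(self) -> list[RegulationTerm]:
        return [t for g in self.genes for blk in self.blocks.get(g, ()) for t in blk]

    def basal_names(self) -> list[str]:
        return [f"b:{g}" for g in self.genes]

    def v_names(self) -> list[str]:
        return [
            _block_v_name(g, blk) for g in self.genes for blk in self.blocks.get(g, ())
        ]

    def k_names(self) -> list[str]:
        names: list[str] = []
        for t in self.terms():
            if t.k_name not in names:
                names.append(t.k_name)
        return names

    def parameter_names(self) -> list[str]:
        """Free parameters in canonical order: basal rates, block rates, k."""
        return self.basal_names() + self.v_names() + self.k_names()

    def is_all_or(self) -> bool:
        return all(len(b) == 1 for g in self.genes for b in self.blocks.get(g, ()))

    def is_all_and(self) -> bool:
        return all(len(self.blocks.get(g, ())) <= 1 for g in self.genes)

    def with_signed(self, signed: bool = True) -> "ODEModelSpec":
        return dataclasses.replace(self, signed=signed)

    def to_json(self) -> str:
        doc = {
            "genes": list(self.genes),
            "variant_id": self.variant_id,
            "signed": self.signed,
            "blocks": {
                g: [[dataclasses.asdict(t) for t in blk] for blk in blks]
                for g, blks in self.blocks.items()
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ODEModelSpec":
        doc = json.loads(text)
        blocks = {
            g: tuple(tuple(RegulationTerm(**t) for t in blk) for blk in blks)
            for g, blks in doc["blocks"].items()
        }
        return cls(
            genes=tuple(doc["genes"]),
            blocks=blocks,
            variant_id=doc["variant_id"],
            signed=doc["signed"],
        )


@dataclasses.dataclass
class ParameterSet:
    """Values for the free parameters of a spec plus fixed alpha and d.

    ``values`` maps parameter names (``b:gene``, ``v:target:...``,
    ``k:regulator:role``) to floats.  ``alpha`` is the Hill exponent shared
    per regulator gene (default 1, not fitted); ``d`` the degradation rates
    (default 1).  In signed (sign-relaxed) mode block rates may be negative:
    the absolute value is the rate and the sign alone selects the form of
    every member fraction (positive = activation, negative = repression),
    overriding the declared term signs.
    """

    values: dict[str, float]
    alpha: dict[str, float] = dataclasses.field(default_factory=dict)
    d: dict[str, float] = dataclasses.field(default_factory=dict)

    def get(self, name: str) -> float:
        try:
            return float(self.values[name])
        except KeyError as exc:
            raise ParameterMismatchError(f"parameter {name!r} not supplied") from exc

    def alpha_of(self, gene: str) -> float:
        return float(self.alpha.get(gene, 1.0))

    def d_of(self, gene: str) -> float:
        return float(self.d.get(gene, 1.0))

    def vector(self, spec: ODEModelSpec) -> np.ndarray:
        return np.array([self.get(n) for n in spec.parameter_names()], dtype=float)

    @classmethod
    def from_vector(
        cls,
        spec: ODEModelSpec,
        theta: np.ndarray,
        alpha: Mapping[str, float] | None = None,
        d: Mapping[str, float] | None = None,
    ) -> "ParameterSet":
        names = spec.parameter_names()
        if len(theta) != len(names):
            raise ParameterMismatchError(
                f"vector length {len(theta)} != {len(names)} parameters"
            )
        return cls(
            values=dict(zip(names, map(float, theta))),
            alpha=dict(alpha or {}),
            d=dict(d or {}),
        )

    def to_json(self) -> str:
        return json.dumps(
            {"values": self.values, "alpha": self.alpha, "d": self.d}, indent=2
        )

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        doc = json.loads(text)
        return cls(values=doc["values"], alpha=doc["alpha"], d=doc["d"])


# ---------------------------------------------------------------------------
# Hill functions

def hill_activation(g: float, f: float, v: float, k: float, alpha: float = 1.0) -> float:
    """v * (g f)^a / (k^a + (g f)^a); defined as 0 when k = g f = 0."""
    x = (g * f) ** alpha
    ka = k ** alpha
    denom = ka + x
    if denom == 0.0:
        return 0.0
    return v * x / denom


def hill_repression(g: float, f: float, v: float, k: float, alpha: float = 1.0) -> float:
    """v * k^a / (k^a + (g f)^a); 0 when k = 0 (repressor always bound)."""
    x = (g * f) ** alpha
    ka = k ** alpha
    denom = ka + x
    if denom == 0.0:
        return 0.0
    return v * ka / denom


# ---------------------------------------------------------------------------
# Logic variant enumeration

def set_partitions(items: Sequence) -> list[list[list]]:
    """All set partitions, ordered all-singletons first, single-block last."""
    items = list(items)
    if not items:
        return [[]]
    parts: list[list[list]] = []

    def extend(prefix: list[list], rest: list) -> None:
        if not rest:
            parts.append([list(b) for b in prefix])
            return
        head, tail = rest[0], rest[1:]
        for i in range(len(prefix)):
            prefix[i].append(head)
            extend(prefix, tail)
            prefix[i].pop()
        prefix.append([head])
        extend(prefix, tail)
        prefix.pop()

    extend([], items)
    # sort: number of blocks descending (singletons first), then by the
    # block-membership signature for a deterministic total order
    def signature(p: list[list]) -> tuple:
        index = {id(it): j for j, it in enumerate(items)}
        labels = {}
        for bi, blk in enumerate(sorted(p, key=lambda b: min(index[id(x)] for x in b))):
            for x in blk:
                labels[index[id(x)]] = bi
        return tuple(labels[j] for j in range(len(items)))

    parts.sort(key=lambda p: (-len(p), signature(p)))
    return parts


def enumerate_logic_variants(
    genes: Sequence[str],
    terms: Iterable[RegulationTerm],
    signed: bool = False,
) -> list[ODEModelSpec]:
    """One spec per combination of per-gene AND-block partitions.

    The count is the product of Bell numbers of each gene's term count;
    variant 1 is all-OR (every block a singleton) and the last variant is
    all-AND (one block per gene).
    """
    genes = tuple(genes)
    by_gene: dict[str, list[RegulationTerm]] = {g: [] for g in genes}
    for t in terms:
        if t.target not in by_gene:
            raise ValueError(f"term target {t.target!r} not in gene list")
        by_gene[t.target].append(t)
    per_gene_partitions = [set_partitions(by_gene[g]) for g in genes]
    specs = []
    for vid, combo in enumerate(itertools.product(*per_gene_partitions), start=1):
        blocks = {
            g: tuple(tuple(blk) for blk in part) for g, part in zip(genes, combo)
        }
        specs.append(
            ODEModelSpec(genes=genes, blocks=blocks, variant_id=vid, signed=signed)
        )
    return specs


def late_l1_terms() -> list[RegulationTerm]:
    """The late-L1 topology: 2 regulators of elt-1 and egl-18, 3 of ceh-16."""
    return [
        RegulationTerm("elt-1", "egl-18", ACTIVATION),
        RegulationTerm("elt-1", "ceh-16", REPRESSION),
        RegulationTerm("egl-18", "elt-1", ACTIVATION),
        RegulationTerm("egl-18", "ceh-16", REPRESSION),
        RegulationTerm("ceh-16", "elt-1", ACTIVATION),
        RegulationTerm("ceh-16", "egl-18", ACTIVATION),
        RegulationTerm("ceh-16", "ceh-16", ACTIVATION, self_flag=True),
    ]


def naive_literature_terms() -> list[RegulationTerm]:
    """Literature network: ELT-1 activates egl-18 and ceh-16, CEH-16 activates egl-18."""
    return [
        RegulationTerm("egl-18", "elt-1", ACTIVATION),
        RegulationTerm("egl-18", "ceh-16", ACTIVATION),
        RegulationTerm("ceh-16", "elt-1", ACTIVATION),
    ]


# ---------------------------------------------------------------------------
# Right-hand side and steady states

def build_rhs(
    spec: ODEModelSpec,
    params: ParameterSet,
    genotype: GenotypeSpec,
) -> Callable[[np.ndarray], np.ndarray]:
    """Derivative function g -> dg/dt for one genotype (reference evaluator).

    This is a direct, readable evaluation of the model used for testing and
    cross-checks; bulk steady-state computation goes through the compiled
    panel evaluator.
    """
    gi = {g: i for i, g in enumerate(spec.genes)}
    f = genotype.as_array()
    if len(f) != len(spec.genes):
        raise ValueError("genotype activity vector does not match gene count")
    b = np.array([params.get(n) for n in spec.basal_names()])
    d = np.array([params.d_of(g) for g in spec.genes])
    blocks = []
    for g in spec.genes:
        for blk in spec.blocks.get(g, ()):
            v = params.get(_block_v_name(g, blk))
            blocks.append((gi[g], v, blk))
    # verify k coverage up front so errors surface at build time
    for t in spec.terms():
        params.get(t.k_name)

    def rhs(state: np.ndarray) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        prod = b.copy()
        for tgt, v, blk in blocks:
            if spec.signed:
                rate, flip = abs(v), v < 0
            else:
                rate, flip = v, False
            val = rate
            for t in blk:
                j = gi[t.regulator]
                # signed mode: v's sign alone selects the form
                act = (not flip) if spec.signed else (t.sign == ACTIVATION)
                hill = hill_activation if act else hill_repression
                val *= hill(state[j], f[j], 1.0, params.get(t.k_name),
                            params.alpha_of(t.regulator))
            prod[tgt] += val
        return prod - d * state

    return rhs


def _encode(spec: ODEModelSpec, params: ParameterSet):
    """Flatten spec + params into plain arrays for the panel kernel."""
    gi = {g: i for i, g in enumerate(spec.genes)}
    n = len(spec.genes)
    b = np.array([params.get(nm) for nm in spec.basal_names()])
    d = np.array([params.d_of(g) for g in spec.genes])
    alpha = np.array([params.alpha_of(g) for g in spec.genes])
    k_names = spec.k_names()
    kidx = {nm: i for i, nm in enumerate(k_names)}
    kv = np.array([params.get(nm) for nm in k_names]) if k_names else np.zeros(0)

    block_target, vb = [], []
    term_reg, term_act, term_kidx, block_ptr = [], [], [], [0]
    for g in spec.genes:
        for blk in spec.blocks.get(g, ()):
            block_target.append(gi[g])
            vb.append(params.get(_block_v_name(g, blk)))
            for t in blk:
                term_reg.append(gi[t.regulator])
                term_act.append(1 if t.sign == ACTIVATION else 0)
                term_kidx.append(kidx[t.k_name])
            block_ptr.append(len(term_reg))
    return (
        b, d,
        np.asarray(vb, dtype=float),
        np.asarray(kv, dtype=float),
        alpha,
        np.asarray(block_target, dtype=np.int64),
        np.asarray(block_ptr, dtype=np.int64),
        np.asarray(term_reg, dtype=np.int64),
        np.asarray(term_act, dtype=np.int64),
        np.asarray(term_kidx, dtype=np.int64),
        bool(spec.signed),
        n,
    )


def _panel_kernel(b, d, vb, kv, alpha, block_target, block_ptr, term_reg,
                  term_act, term_kidx, signed, F, G0, dt, t_max, tol):
    """Integrate every genotype column to its fixed point.

    Exponential-Euler forward integration: the linear degradation part is
    handled exactly each step, so the scheme's fixed points coincide with
    the ODE's and iterates stay non-negative.  Returns (S, converged).
    """
    m = F.shape[0]
    n = b.shape[0]
    nb = vb.shape[0]
    S = np.zeros((m, n))
    conv = np.zeros(m, dtype=np.bool_)
    max_steps = int(t_max / dt)
    p = np.zeros(n)
    for j in range(m):
        g = G0[j].copy()
        ok = False
        for _step in range(max_steps):
            for i in range(n):
                p[i] = b[i]
            for bl in range(nb):
                v = vb[bl]
                if v == 0.0:
                    continue
                if signed and v < 0.0:
                    rate = -v
                    flip = True
                else:
                    rate = v
                    flip = False
                val = rate
                for tt in range(block_ptr[bl], block_ptr[bl + 1]):
                    reg = term_reg[tt]
                    a = alpha[reg]
                    x = (g[reg] * F[j, reg]) ** a
                    ka = kv[term_kidx[tt]] ** a
                    denom = ka + x
                    if signed:
                        # sign-relaxed mode: the block rate's sign selects the
                        # form (positive = activation, negative = repression)
                        act = not flip
                    else:
                        act = term_act[tt] == 1
                    if denom == 0.0:
                        frac = 0.0
                    elif act:
                        frac = x / denom
                    else:
                        frac = ka / denom
                    val *= frac
                p[block_target[bl]] += val
            maxrel = 0.0
            for i in range(n):
                rate_i = p[i] - d[i] * g[i]
                scale = g[i] if g[i] > 1.0 else 1.0
                rel = abs(rate_i) / scale
                if rel > maxrel:
                    maxrel = rel
                target = p[i] / d[i]
                g[i] = target + (g[i] - target) * np.exp(-d[i] * dt)
            if maxrel < tol:
                ok = True
                break
            if not np.isfinite(maxrel):
                break
        S[j] = g
        conv[j] = ok
    return S, conv


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _panel_kernel_jit = njit(cache=True)(_panel_kernel)
except Exception:  # pragma: no cover
    _panel_kernel_jit = _panel_kernel


class CompiledModel:
    """Spec + parameters flattened for fast repeated steady-state panels.

    Used by the samplers, which mutate the parameter vector in place between
    evaluations via :meth:`set_vector`.
    """

    def __init__(self, spec: ODEModelSpec, params: ParameterSet):
        self.spec = spec
        self.names = spec.parameter_names()
        (self.b, self.d, self.vb, self.kv, self.alpha, self.block_target,
         self.block_ptr, self.term_reg, self.term_act, self.term_kidx,
         self.signed, self.n) = _encode(spec, params)
        self._nb = len(self.vb)

    def set_vector(self, theta: np.ndarray) -> None:
        n, nb = self.n, self._nb
        self.b[:] = theta[:n]
        self.vb[:] = theta[n:n + nb]
        if len(self.kv):
            self.kv[:] = theta[n + nb:]

    def panel(
        self,
        F: np.ndarray,
        G0: np.ndarray,
        dt: float = 0.1,
        t_max: float = 1e4,
        tol: float = 1e-8,
    ) -> tuple[np.ndarray, np.ndarray]:
        S, conv = _panel_kernel_jit(
            self.b, self.d, self.vb, self.kv, self.alpha, self.block_target,
            self.block_ptr, self.term_reg, self.term_act, self.term_kidx,
            self.signed, F, G0, float(dt), float(t_max), float(tol),
        )
        return S, conv


def steady_state(
    spec: ODEModelSpec,
    params: ParameterSet,
    genotype: GenotypeSpec,
    g0: Sequence[float] | np.ndarray,
    dt: float = 0.1,
    t_max: float = 1e4,
    tol: float = 1e-8,
) -> np.ndarray:
    """Fixed point reached by forward integration from ``g0``.

    Integrates until ``max_i |dg_i/dt| / max(g_i, 1) < tol`` or ``t_max``;
    raises :class:`SteadyStateError` (with the trajectory tail attached) on
    non-convergence.
    """
    g0 = np.asarray(g0, dtype=float)
    if not np.all(np.isfinite(g0)) or np.any(g0 < 0):
        raise ValueError("g0 must be finite and non-negative")
    cm = CompiledModel(spec, params)
    F = genotype.as_array()[None, :]
    S, conv = cm.panel(F, g0[None, :].copy(), dt=dt, t_max=t_max, tol=tol)
    if not conv[0]:
        rhs = build_rhs(spec, params, genotype)
        raise SteadyStateError(
            f"no steady state within t_max={t_max} for genotype "
            f"{genotype.name!r} (final state {S[0]})",
            state=S[0],
            rates=rhs(np.nan_to_num(S[0], nan=0.0, posinf=1e300)),
        )
    return S[0]


def genotype_panel(
    spec: ODEModelSpec,
    params: ParameterSet,
    genotypes: Sequence[GenotypeSpec],
    init: np.ndarray | Sequence[Sequence[float]],
    dt: float = 0.1,
    t_max: float = 1e4,
    tol: float = 1e-8,
) -> np.ndarray:
    """Steady-state matrix S (genes x genotypes); ``init`` is per-genotype g0."""
    init = np.asarray(init, dtype=float)
    if init.ndim == 1:
        init = np.tile(init, (len(genotypes), 1))
    cm = CompiledModel(spec, params)
    F = np.stack([gt.as_array() for gt in genotypes])
    S, conv = cm.panel(F, init.copy(), dt=dt, t_max=t_max, tol=tol)
    if not conv.all():
        bad = [genotypes[i].name for i in np.flatnonzero(~conv)]
        raise SteadyStateError(
            f"no steady state for genotype(s) {bad}", state=S.T, rates=None
        )
    return S.T.copy()
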