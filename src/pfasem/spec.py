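"""Declarative linear Gaussian structural equation models.

A model is written as a single linear system over *all* variables (observed
and latent),

    v = m + A v + e,        e ~ N(0, S),

where ``A`` collects directed-edge coefficients (factor loadings, structural
regressions, covariate effects), ``S`` collects bidirected-edge parameters
(residual variances on the diagonal, residual covariances off it) and ``m``
collects intercepts.  Because the directed graph is required to be acyclic,
``I - A`` is invertible and the model-implied moments over the observed
variables are

    mu(theta)    = [(I - A)^-1 m]_obs
    Sigma(theta) = [(I - A)^-1 S (I - A)^-T]_obs.

This one representation serves every model variant in the package: latent
exposures with error-prone indicators, local-dependence factors, exogenous
covariates with freely estimated moments, and equality-constrained effects
(via named parameter groups that share a single free value).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Variable",
    "Parameter",
    "SEMSpec",
    "ModelMoments",
    "SpecError",
    "build_spec",
    "fixed",
    "free",
]

SCHEMA = "pfasem-sem/1"

OBSERVED = "observed"
LATENT = "latent"
KINDS = (OBSERVED, LATENT)
ROLES = ("indicator", "outcome", "covariate", "latent-exposure",
         "local-dependence-factor", "other")


class SpecError(ValueError):
    """A structural problem in a model specification."""


@dataclass(frozen=True)
class Variable:
    """A named model variable, observed or latent."""

    name: str
    kind: str = OBSERVED
    role: str = "other"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SpecError(f"unknown variable kind {self.kind!r}")
        if self.role not in ROLES:
            raise SpecError(f"unknown variable role {self.role!r}")


@dataclass
class Parameter:
    """A single model parameter.

    ``value`` is the start value when free and the constant when fixed.
    Parameters sharing a ``group`` label are constrained equal and occupy a
    single slot in the free-parameter vector.
    """

    label: str
    free: bool = True
    value: float = 0.0
    group: str | None = None


def free(label: str, value: float = 0.0, group: str | None = None) -> Parameter:
    return Parameter(label, free=True, value=value, group=group)


def fixed(label: str, value: float) -> Parameter:
    return Parameter(label, free=False, value=value)


@dataclass
class ModelMoments:
    """Model-implied mean vector and covariance over observed variables."""

    mu: np.ndarray
    sigma: np.ndarray
    names: list

    def as_series(self) -> pd.Series:
        return pd.Series(self.mu, index=self.names)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sigma, index=self.names, columns=self.names)


class SEMSpec:
    """A linear Gaussian SEM over named variables.

    Parameters
    ----------
    variables : sequence of Variable
    directed : sequence of (source, target, Parameter)
        Regression/loading coefficients; the graph they form must be acyclic.
    bidirected : sequence of (a, b, Parameter)
        ``a == b`` entries are residual variances, ``a != b`` residual
        covariances.  Pairs absent from the list are fixed at zero.
    intercepts : mapping name -> Parameter
        One intercept (mean parameter) per non-covariate variable; exogenous
        covariate means live here too when the covariate-moment block is
        modeled.

    Specs are treated as immutable once built; derived structures are cached.
    """

    def __init__(self, variables, directed=(), bidirected=(), intercepts=None):
        self.variables = list(variables)
        self.directed = [(s, t, p) for (s, t, p) in directed]
        self.bidirected = [(a, b, p) for (a, b, p) in bidirected]
        self.intercepts = dict(intercepts or {})
        self._compiled = None

    # ------------------------------------------------------------------ #
    # basic views
    # ------------------------------------------------------------------ #
    @property
    def names(self):
        return [v.name for v in self.variables]

    @property
    def observed_names(self):
        return [v.name for v in self.variables if v.kind == OBSERVED]

    @property
    def latent_names(self):
        return [v.name for v in self.variables if v.kind == LATENT]

    def variable(self, name):
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    # ------------------------------------------------------------------ #
    # validation
    # ------------------------------------------------------------------ #
    def validate(self):
        """Return a list of human-readable invariant violations (never raises)."""
        out = []
        names = self.names
        seen = set()
        for n in names:
            if n in seen:
                out.append(f"duplicate variable name {n!r}")
            seen.add(n)

        def known(n, where):
            if n not in seen:
                out.append(f"{where} references unknown variable {n!r}")
                return False
            return True

        edge_keys = set()
        for s, t, p in self.directed:
            if known(s, f"directed edge {p.label}") and known(t, f"directed edge {p.label}"):
                if (s, t) in edge_keys:
                    out.append(f"duplicate directed edge {s}->{t}")
                edge_keys.add((s, t))
        bi_keys = set()
        for a, b, p in self.bidirected:
            if known(a, f"bidirected edge {p.label}") and known(b, f"bidirected edge {p.label}"):
                key = frozenset((a, b))
                if key in bi_keys:
                    out.append(f"duplicate bidirected edge {a}<->{b}")
                bi_keys.add(key)
        for n, p in self.intercepts.items():
            known(n, f"intercept {p.label}")

        for v in self.variables:
            if v.role == "covariate" and v.kind != OBSERVED:
                out.append(f"covariate {v.name!r} declared latent")

        # acyclicity of the directed part
        if self._topological_order() is None:
            out.append("directed-edge graph contains a cycle")

        # every variable needs a (co)variance entry for its own residual
        var_of = {}
        for a, b, p in self.bidirected:
            if a == b:
                var_of[a] = p
        for v in self.variables:
            if v.name not in var_of:
                out.append(f"no residual-variance parameter for {v.name!r}")

        # variances positive
        for n, p in var_of.items():
            if not p.free and p.value <= 0:
                out.append(f"fixed variance {p.label!r} of {n!r} is not positive")
            if p.free and p.value <= 0:
                out.append(f"start value of free variance {p.label!r} is not positive")

        # latent scale anchoring: a fixed nonzero outgoing loading, or fixed variance
        for v in self.variables:
            if v.kind != LATENT:
                continue
            anchored = any(
                s == v.name and not p.free and p.value != 0
                for s, t, p in self.directed
            )
            pvar = var_of.get(v.name)
            if pvar is not None and not pvar.free:
                anchored = True
            if not anchored:
                out.append(f"latent {v.name!r} has no scale anchor "
                           "(fixed loading or fixed variance)")

        # equality groups must not mix variances with other parameters,
        # nor free with fixed members
        groups = {}
        for kind, p in self._iter_params():
            if p.group is None:
                continue
            info = groups.setdefault(p.group, {"kinds": set(), "free": set()})
            info["kinds"].add("variance" if kind == "variance" else "other")
            info["free"].add(p.free)
        for g, info in groups.items():
            if len(info["kinds"]) > 1:
                out.append(f"equality group {g!r} mixes variances with other parameters")
            if len(info["free"]) > 1:
                out.append(f"equality group {g!r} mixes free and fixed parameters")
        return out

    def _iter_params(self):
        for s, t, p in self.directed:
            yield "directed", p
        for a, b, p in self.bidirected:
            yield ("variance" if a == b else "covariance"), p
        for n, p in self.intercepts.items():
            yield "intercept", p

    def _topological_order(self):
        """Kahn topological order over variable indices, or None on a cycle."""
        idx = {n: i for i, n in enumerate(self.names)}
        k = len(idx)
        children = [[] for _ in range(k)]
        indeg = [0] * k
        for s, t, _ in self.directed:
            if s in idx and t in idx:
                children[idx[s]].append(idx[t])
                indeg[idx[t]] += 1
        stack = [i for i in range(k) if indeg[i] == 0]
        order = []
        while stack:
            i = stack.pop()
            order.append(i)
            for j in children[i]:
                indeg[j] -= 1
                if indeg[j] == 0:
                    stack.append(j)
        return order if len(order) == k else None

    # ------------------------------------------------------------------ #
    # free-parameter indexing
    # ------------------------------------------------------------------ #
    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        idx = {n: i for i, n in enumerate(self.names)}
        k = len(idx)
        obs_idx = np.array([i for i, v in enumerate(self.variables)
                            if v.kind == OBSERVED], dtype=int)

        slots = {}          # group label or param id -> slot
        labels, starts, is_var = [], [], []

        def slot_for(p, variance):
            key = ("g", p.group) if p.group is not None else ("p", id(p))
            if key not in slots:
                slots[key] = len(labels)
                labels.append(p.group if p.group is not None else p.label)
                starts.append(p.value)
                is_var.append(variance)
            return slots[key]

        entries = []        # (matrix, i, j, slot or -1, fixed value)
        for s, t, p in self.directed:
            sl = slot_for(p, False) if p.free else -1
            entries.append(("A", idx[t], idx[s], sl, p.value))
        for a, b, p in self.bidirected:
            variance = a == b
            sl = slot_for(p, variance) if p.free else -1
            entries.append(("S", idx[a], idx[b], sl, p.value))
        for n, p in self.intercepts.items():
            sl = slot_for(p, False) if p.free else -1
            entries.append(("m", idx[n], 0, sl, p.value))

        comp = {
            "k": k,
            "obs_idx": obs_idx,
            "labels": labels,
            "starts": np.asarray(starts, dtype=float),
            "is_variance": np.asarray(is_var, dtype=bool),
        }
        for mat in ("A", "S", "m"):
            sub = [e for e in entries if e[0] == mat]
            comp[mat] = {
                "rows": np.array([e[1] for e in sub], dtype=int),
                "cols": np.array([e[2] for e in sub], dtype=int),
                "slot": np.array([e[3] for e in sub], dtype=int),
                "fixed": np.array([e[4] for e in sub], dtype=float),
            }
        self._compiled = comp
        return comp

    @property
    def free_labels(self):
        return list(self._compile()["labels"])

    @property
    def variance_mask(self):
        """Boolean mask over the free-parameter vector: True for variances."""
        return self._compile()["is_variance"].copy()

    def free_parameter_count(self) -> int:
        """Number of free parameters, counting each equality group once."""
        return len(self._compile()["labels"])

    def start_theta(self) -> np.ndarray:
        return self._compile()["starts"].copy()

    def model_df(self) -> int:
        """Degrees of freedom under the mean-structure convention.

        With p observed variables the saturated model has p means plus
        p(p+1)/2 covariances, i.e. p(p+3)/2 moments; df is that count minus
        the number of free parameters q.  Exogenous covariates contribute
        their full moment block to both sides, so they cancel.
        """
        p = len(self.observed_names)
        return p * (p + 3) // 2 - self.free_parameter_count()

    # ------------------------------------------------------------------ #
    # moments and simulation
    # ------------------------------------------------------------------ #
    def matrices(self, theta):
        """Return (A, S, m) over all variables at the given free-parameter vector."""
        comp = self._compile()
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(comp["labels"]),):
            raise ValueError(
                f"theta has length {theta.size}, expected {len(comp['labels'])}")
        bad = comp["is_variance"] & ~(theta > 0)
        if bad.any():
            names = [comp["labels"][i] for i in np.flatnonzero(bad)]
            raise ValueError(f"non-positive variance parameter(s): {names}")
        k = comp["k"]
        A = np.zeros((k, k))
        S = np.zeros((k, k))
        m = np.zeros(k)
        for mat, target in (("A", A), ("S", S)):
            e = comp[mat]
            vals = np.where(e["slot"] >= 0, theta[e["slot"]], e["fixed"])
            target[e["rows"], e["cols"]] = vals
        e = comp["m"]
        m[e["rows"]] = np.where(e["slot"] >= 0, theta[e["slot"]], e["fixed"])
        S = S + S.T - np.diag(np.diag(S))
        return A, S, m

    def implied_moments(self, theta) -> ModelMoments:
        """Model-implied mean and covariance over the observed variables."""
        A, S, m = self.matrices(theta)
        k = A.shape[0]
        ima = np.eye(k) - A
        B = np.linalg.solve(ima, np.eye(k))
        mu = B @ m
        sigma = B @ S @ B.T
        obs = self._compile()["obs_idx"]
        return ModelMoments(mu[obs], sigma[np.ix_(obs, obs)],
                            [self.names[i] for i in obs])

    def simulate(self, theta, n, rng) -> pd.DataFrame:
        """Draw n rows from the structural equations at theta.

        Residuals are drawn jointly from N(0, S) and the linear system
        ``v = m + A v + e`` is solved; with an acyclic ``A`` this is the
        structural-equation data-generating process.  Returns the observed
        columns only.
        """
        A, S, m = self.matrices(theta)
        k = A.shape[0]
        w, V = np.linalg.eigh((S + S.T) / 2)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("bidirected covariance matrix S is not PSD at theta")
        half = V * np.sqrt(np.clip(w, 0, None))
        e = rng.standard_normal((n, k)) @ half.T
        v = np.linalg.solve(np.eye(k) - A, (m + e).T).T
        obs = self._compiled["obs_idx"]
        return pd.DataFrame(v[:, obs],
                            columns=[self.names[i] for i in obs])

    # ------------------------------------------------------------------ #
    # constraint editing (returns new specs; the original is untouched)
    # ------------------------------------------------------------------ #
    def with_equality(self, labels, group):
        """Return a copy in which the named free parameters share one value."""
        labels = set(labels)
        found = set()

        def rep(p):
            if p.label in labels:
                found.add(p.label)
                if not p.free:
                    raise SpecError(f"cannot constrain fixed parameter {p.label!r}")
                return replace(p, group=group)
            return p

        directed = [(s, t, rep(p)) for s, t, p in self.directed]
        bidirected = [(a, b, rep(p)) for a, b, p in self.bidirected]
        intercepts = {n: rep(p) for n, p in self.intercepts.items()}
        missing = labels - found
        if missing:
            raise SpecError(f"no parameter(s) labelled {sorted(missing)}")
        return SEMSpec(self.variables, directed, bidirected, intercepts)

    def with_fixed(self, values: dict):
        """Return a copy with the named parameters fixed at given constants."""
        values = dict(values)
        found = set()

        def rep(p):
            if p.label in values:
                found.add(p.label)
                return Parameter(p.label, free=False, value=values[p.label])
            return p

        directed = [(s, t, rep(p)) for s, t, p in self.directed]
        bidirected = [(a, b, rep(p)) for a, b, p in self.bidirected]
        intercepts = {n: rep(p) for n, p in self.intercepts.items()}
        missing = set(values) - found
        if missing:
            raise SpecError(f"no parameter(s) labelled {sorted(missing)}")
        return SEMSpec(self.variables, directed, bidirected, intercepts)

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_dict(self):
        def pd_(p):
            d = {"label": p.label, "free": p.free, "value": p.value}
            if p.group is not None:
                d["group"] = p.group
            return d

        return {
            "schema": SCHEMA,
            "variables": [{"name": v.name, "kind": v.kind, "role": v.role}
                          for v in self.variables],
            "directed": [{"from": s, "to": t, **pd_(p)}
                         for s, t, p in self.directed],
            "bidirected": [{"v1": a, "v2": b, **pd_(p)}
                           for a, b, p in self.bidirected],
            "intercepts": [{"var": n, **pd_(p)}
                           for n, p in self.intercepts.items()],
        }

    @classmethod
    def from_dict(cls, d):
        if d.get("schema") != SCHEMA:
            raise SpecError(f"unknown spec schema {d.get('schema')!r}")

        def par(e):
            return Parameter(e["label"], free=e.get("free", True),
                             value=float(e.get("value", 0.0)),
                             group=e.get("group"))

        return cls(
            [Variable(v["name"], v.get("kind", OBSERVED), v.get("role", "other"))
             for v in d["variables"]],
            [(e["from"], e["to"], par(e)) for e in d["directed"]],
            [(e["v1"], e["v2"], par(e)) for e in d["bidirected"]],
            {e["var"]: par(e) for e in d["intercepts"]},
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    @classmethod
    def from_json(cls, s: str):
        return cls.from_dict(json.loads(s))


def build_spec(variables, directed=(), bidirected=(), intercepts=None) -> SEMSpec:
    """Construct and validate an SEMSpec; raise SpecError on any violation."""
    spec = SEMSpec(variables, directed, bidirected, intercepts)
    problems = spec.validate()
    if problems:
        raise SpecError("; ".join(problems))
    return spec
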