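"""Input importance and model distillation for the learned committor.

Permutation importance: the shooting loss of the trained committor model is
compared between the original dataset and datasets in which one descriptor
column is randomly permuted; the mean relative loss increase over the
permutations is the importance score.  Scores are computed separately on the
low-progress subset {x | pB(x) <= 0.2} and the high-progress subset
{x | pB(x) >= 0.2} (and on the full set), because different descriptors
matter at different stages of the association.

Distillation: a two-contact closed-form committor surrogate

    pB2D(sG, sV) = sG * exp(-5.9 * (sG * sV - 0.04) * (sV - 1))

(on the contact switches of the G225:G225' and V217:V217' pairs), plus a
symbolic-regression fitter that evolves small expression trees against the
binomial shooting loss with a complexity penalty, with a parametric-family
fallback fitted by maximum likelihood.

Note on the expression: the printed form of the distilled committor is
typographically ambiguous about the grouping of its exponent; the parse used
here, with constants 5.9, 0.04 and 1, is the only grouping consistent with
the model's two documented qualitative properties (the G225 contact dominates,
and pB2D can exceed 0.5 with the V217 contact fully absent).  See
docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

# statistics used for committor comparisons live in .stats; re-exported here
# because they belong to this module's public surface
from .stats import proportions_ztest, binomial_ci  # noqa: F401

__all__ = ["permutation_importance", "pb2d", "fit_distilled_model",
           "DistilledModel", "Expr", "proportions_ztest", "binomial_ci"]

_EPS = 1e-9

PB2D_CONSTANTS = (5.9, 0.04, 1.0)


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------

def _nll(p, n_a, n_b):
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.sum(n_a * np.log(1.0 - p) + n_b * np.log(p)))


def permutation_importance(model, X, n_a, n_b, split_threshold: float = 0.2,
                           n_perm: int = 100, seed: int = 0) -> pd.DataFrame:
    """Relative importance scores of each descriptor for the committor model.

    For each subset (pB <= threshold, pB >= threshold, all), the reference
    shooting loss l_ref is compared with the loss after randomly permuting a
    single descriptor column (within the subset), over ``n_perm``
    permutations.  The score is the mean of (l_perm - l_ref)/l_ref, its
    spread the SD over permutations.  Returns a tidy DataFrame with columns
    descriptor, subset, score, sd.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    pb = model.predict(X)
    subsets = {
        "low": pb <= split_threshold,
        "high": pb >= split_threshold,
        "all": np.ones(len(X), dtype=bool),
    }
    rng = np.random.default_rng(seed)
    rows = []
    for name, mask in subsets.items():
        if not mask.any():
            warnings.warn(f"subset {name!r} is empty; scores omitted")
            continue
        Xs, na_s, nb_s = X[mask], n_a[mask], n_b[mask]
        lref = _nll(model.predict(Xs), na_s, nb_s)
        if lref <= 0:
            warnings.warn(f"vanishing reference loss on subset {name!r}")
            lref = _EPS
        for j in range(X.shape[1]):
            diffs = np.empty(n_perm)
            Xp = Xs.copy()
            for r in range(n_perm):
                Xp[:, j] = Xs[rng.permutation(len(Xs)), j]
                diffs[r] = (_nll(model.predict(Xp), na_s, nb_s) - lref) / lref
            rows.append({"descriptor": j, "subset": name,
                         "score": diffs.mean(), "sd": diffs.std()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distilled two-contact committor
# ---------------------------------------------------------------------------

def pb2d(sigma_g225, sigma_v217):
    """Distilled two-contact committor surrogate (clipped to [0, 1]).

    Inputs are the contact switching values of the G225:G225' and V217:V217'
    pairs, each in [0, 1].
    """
    sg = np.asarray(sigma_g225, dtype=float)
    sv = np.asarray(sigma_v217, dtype=float)
    if np.any((sg < 0) | (sg > 1)) or np.any((sv < 0) | (sv > 1)):
        raise ValueError("contact switch values must lie in [0, 1]")
    a, b, c = PB2D_CONSTANTS
    out = np.clip(sg * np.exp(-a * (sg * sv - b) * (sv - c)), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# symbolic distillation
# ---------------------------------------------------------------------------

@dataclass
class Expr:
    """A small expression tree over {+, -, *, /, exp, pow}, variables and
    constants, with guarded evaluation."""

    op: str                     # 'var', 'const', '+', '-', '*', '/', 'pow', 'exp'
    value: float = 0.0          # constant value or variable index
    children: tuple = ()

    def eval(self, X: np.ndarray) -> np.ndarray:
        if self.op == "var":
            return X[:, int(self.value)]
        if self.op == "const":
            return np.full(len(X), self.value)
        args = [c.eval(X) for c in self.children]
        if self.op == "+":
            return args[0] + args[1]
        if self.op == "-":
            return args[0] - args[1]
        if self.op == "*":
            return args[0] * args[1]
        if self.op == "/":
            denom = np.where(np.abs(args[1]) < 1e-6,
                             np.copysign(1e-6, args[1] + 1e-30), args[1])
            return args[0] / denom
        if self.op == "exp":
            return np.exp(np.clip(args[0], -50.0, 50.0))
        if self.op == "pow":
            base = np.maximum(np.abs(args[0]), 1e-9)
            return base ** np.clip(args[1], -4.0, 4.0)
        raise ValueError(f"unknown op {self.op!r}")

    def n_ops(self) -> int:
        if self.op in ("var", "const"):
            return 0
        return 1 + sum(c.n_ops() for c in self.children)

    def nodes(self) -> list["Expr"]:
        out = [self]
        for c in self.children:
            out.extend(c.nodes())
        return out

    def copy(self) -> "Expr":
        return Expr(self.op, self.value, tuple(c.copy() for c in self.children))

    def render(self) -> str:
        if self.op == "var":
            return f"x{int(self.value)}"
        if self.op == "const":
            return f"{self.value:.4g}"
        if self.op == "exp":
            return f"exp({self.children[0].render()})"
        if self.op == "pow":
            return f"pow({self.children[0].render()}, {self.children[1].render()})"
        return f"({self.children[0].render()} {self.op} {self.children[1].render()})"


_BINARY = ("+", "-", "*", "/", "pow")


def _random_expr(rng, n_vars: int, depth: int) -> Expr:
    if depth <= 0 or rng.random() < 0.35:
        if rng.random() < 0.6:
            return Expr("var", rng.integers(0, n_vars))
        return Expr("const", rng.normal(0.0, 2.0))
    if rng.random() < 0.2:
        return Expr("exp", children=(_random_expr(rng, n_vars, depth - 1),))
    op = _BINARY[rng.integers(0, len(_BINARY))]
    return Expr(op, children=(_random_expr(rng, n_vars, depth - 1),
                              _random_expr(rng, n_vars, depth - 1)))


def _mutate(expr: Expr, rng, n_vars: int) -> Expr:
    new = expr.copy()
    nodes = new.nodes()
    target = nodes[rng.integers(0, len(nodes))]
    if target.op == "const" and rng.random() < 0.6:
        target.value += rng.normal(0.0, 0.5)
        return new
    repl = _random_expr(rng, n_vars, depth=2)
    target.op = repl.op
    target.value = repl.value
    target.children = repl.children
    return new


@dataclass
class DistilledModel:
    """A distilled committor surrogate: a symbolic expression or a fitted
    parametric family, with the complexity and validation error recorded."""

    kind: str                       # 'symbolic', 'parametric' or 'constant'
    expression: Expr | None
    params: np.ndarray | None
    input_indices: tuple
    complexity: int
    train_loss: float
    validation_error: float = np.nan
    rendering: str = ""

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, list(self.input_indices)]
        if self.kind == "symbolic":
            out = self.expression.eval(X)
        elif self.kind == "parametric":
            a, b, c = self.params
            s1, s2 = X[:, 0], X[:, 1]
            out = s1 * np.exp(np.clip(-a * (s1 * s2 - b) * (s2 - c), -50, 50))
        else:
            out = np.full(len(X), self.params[0])
        return np.clip(out, 0.0, 1.0)


def _fit_parametric(X, n_a, n_b, start=(5.9, 0.04, 1.0)):
    s1, s2 = X[:, 0], X[:, 1]

    def nll(theta):
        a, b, c = theta
        p = np.clip(s1 * np.exp(np.clip(-a * (s1 * s2 - b) * (s2 - c), -50, 50)),
                    _EPS, 1 - _EPS)
        return -np.sum(n_a * np.log(1 - p) + n_b * np.log(p))

    res = minimize(nll, np.asarray(start, dtype=float), method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
    return res.x, float(res.fun)


def fit_distilled_model(X, n_a, n_b, candidate_inputs=(0, 1),
                        regularization: float = 0.001,
                        max_generations: int = 500, seed: int = 0,
                        population: int = 8) -> DistilledModel:
    """Fit a small closed-form committor on shooting outcomes.

    Evolves expression trees over the candidate input contacts with a
    (1+lambda) strategy, minimizing the mean binomial shooting loss plus
    ``regularization`` times the number of elementary operations.  A
    parametric family s1*exp(-a(s1*s2-b)(s2-c)) is always fitted for
    comparison; the model with the lower penalized loss wins.  If neither
    beats the constant model, the constant is returned with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))[:, list(candidate_inputs)]
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    n_trials = (n_a + n_b).sum()
    rng = np.random.default_rng(seed)
    n_vars = X.shape[1]

    def penalized(expr: Expr) -> float:
        p = np.clip(expr.eval(X), _EPS, 1 - _EPS)
        nll = -np.sum(n_a * np.log(1 - p) + n_b * np.log(p)) / n_trials
        return nll + regularization * expr.n_ops()

    best = _random_expr(rng, n_vars, depth=3)
    best_cost = penalized(best)
    for _ in range(max_generations):
        for _ in range(population):
            cand = _mutate(best, rng, n_vars)
            cost = penalized(cand)
            if cost <= best_cost:
                best, best_cost = cand, cost

    theta, par_nll = _fit_parametric(X, n_a, n_b)
    par_cost = par_nll / n_trials + regularization * 4   # 4 elementary ops

    p_const = np.clip(n_b.sum() / n_trials, _EPS, 1 - _EPS)
    const_cost = float(-(n_a.sum() * np.log(1 - p_const)
                         + n_b.sum() * np.log(p_const)) / n_trials)

    if min(best_cost, par_cost) >= const_cost:
        warnings.warn("no expression beats the constant model")
        return DistilledModel(kind="constant", expression=None,
                              params=np.array([p_const]),
                              input_indices=tuple(candidate_inputs),
                              complexity=0, train_loss=const_cost,
                              rendering=f"{p_const:.4g}")
    if par_cost <= best_cost:
        return DistilledModel(kind="parametric", expression=None, params=theta,
                              input_indices=tuple(candidate_inputs),
                              complexity=4, train_loss=par_cost,
                              rendering=("s1*exp(-%.4g*(s1*s2-%.4g)*(s2-%.4g))"
                                         % tuple(theta)))
    return DistilledModel(kind="symbolic", expression=best, params=None,
                          input_indices=tuple(candidate_inputs),
                          complexity=best.n_ops(), train_loss=best_cost,
                          rendering=best.render())
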