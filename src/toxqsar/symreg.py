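"""Genetic-programming symbolic regression with explicit complexity control.

Expression trees over {+, -, *, protected /}, descriptor leaves and real
constants.  Fitness is training RMSE (after per-individual linear scaling,
which folds an affine a + b*tree into every candidate) plus a parsimony
penalty proportional to node count.  Generational evolution with tournament
selection, subtree crossover/mutation, elitism, and a final least-squares
refit of all numeric constants in the champion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .datamodel import ValidationError

_DIV_EPS = 1e-6


@dataclass
class SRConfig:
    population: int = 500
    generations: int = 40
    tournament: int = 7
    p_crossover: float = 0.7
    p_subtree_mutation: float = 0.15
    p_insert_mutation: float = 0.1
    p_const_mutation: float = 0.05
    parsimony: float = 0.005        # lambda_c, per node
    max_depth: int = 6
    max_nodes: int = 25
    stagnation: int = 10            # generations without improvement before
                                    # the worst half is re-randomized
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_crossover, self.p_subtree_mutation,
                  self.p_insert_mutation, self.p_const_mutation):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.parsimony < 0:
            raise ValidationError("parsimony weight must be >= 0")
        if self.population < 1:
            raise ValidationError("population must be non-empty")


# tree nodes: ("add"|"sub"|"mul"|"div", left, right) | ("var", j) | ("const", v)
_BINARY = ("add", "sub", "mul", "div")
_OP_CHARS = {"add": "+", "sub": "-", "mul": "*", "div": "/"}


@dataclass
class Expression:
    """Immutable expression tree bound to a column layout."""
    tree: tuple
    columns: list[str]
    fitness: Optional[float] = None
    rmse: Optional[float] = None

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.columns):
            raise ValidationError("column count mismatch")
        return _eval(self.tree, X)

    def complexity(self) -> tuple[int, int]:
        return _nodes(self.tree), _depth(self.tree)

    def to_prefix(self) -> str:
        return _prefix(self.tree)

    def to_infix(self) -> str:
        return _infix(self.tree)

    @classmethod
    def from_prefix(cls, s: str, columns: list[str]) -> "Expression":
        tokens = s.replace("(", " ( ").replace(")", " ) ").split()
        tree, rest = _parse(tokens, columns)
        if rest:
            raise ValidationError("trailing tokens in prefix expression")
        return cls(tree, list(columns))


def _eval(node, X):
    op = node[0]
    if op == "var":
        j = node[1]
        if j >= X.shape[1]:
            raise ValidationError(f"expression references column {j} "
                                  f"beyond input width {X.shape[1]}")
        return X[:, j]
    if op == "const":
        return np.full(X.shape[0], float(node[1]))
    a = _eval(node[1], X)
    b = _eval(node[2], X)
    if op == "add":
        return a + b
    if op == "sub":
        return a - b
    if op == "mul":
        return a * b
    # protected division: x/y if |y| > eps else 1
    return np.where(np.abs(b) > _DIV_EPS, a / np.where(b == 0, 1.0, b), 1.0)


def _nodes(node) -> int:
    if node[0] in ("var", "const"):
        return 1
    return 1 + _nodes(node[1]) + _nodes(node[2])


def _depth(node) -> int:
    if node[0] in ("var", "const"):
        return 1
    return 1 + max(_depth(node[1]), _depth(node[2]))


def _prefix(node) -> str:
    if node[0] == "var":
        return f"x{node[1]}"
    if node[0] == "const":
        return f"{node[1]:.12g}"
    return f"({_OP_CHARS[node[0]]} {_prefix(node[1])} {_prefix(node[2])})"


def _infix(node) -> str:
    if node[0] == "var":
        return f"x{node[1]}"
    if node[0] == "const":
        return f"{node[1]:.6g}"
    return f"({_infix(node[1])} {_OP_CHARS[node[0]]} {_infix(node[2])})"


_CHAR_OPS = {v: k for k, v in _OP_CHARS.items()}


def _parse(tokens, columns):
    tok, rest = tokens[0], tokens[1:]
    if tok == "(":
        op = _CHAR_OPS[rest[0]]
        a, rest = _parse(rest[1:], columns)
        b, rest = _parse(rest, columns)
        if rest[0] != ")":
            raise ValidationError("unbalanced parentheses")
        return (op, a, b), rest[1:]
    if tok.startswith("x") and tok[1:].isdigit():
        return ("var", int(tok[1:])), rest
    if tok in columns:
        return ("var", columns.index(tok)), rest
    return ("const", float(tok)), rest


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def _random_tree(rng, p, depth, full):
    if depth <= 1 or (not full and rng.random() < 0.3):
        if rng.random() < 0.8:
            return ("var", int(rng.integers(p)))
        return ("const", float(rng.uniform(-1, 1)))
    op = _BINARY[int(rng.integers(len(_BINARY)))]
    return (op, _random_tree(rng, p, depth - 1, full),
            _random_tree(rng, p, depth - 1, full))


def _all_nodes(node, path=()):
    yield path, node
    if node[0] in _BINARY:
        yield from _all_nodes(node[1], path + (1,))
        yield from _all_nodes(node[2], path + (2,))


def _replace(node, path, sub):
    if not path:
        return sub
    children = [node[1], node[2]]
    children[path[0] - 1] = _replace(children[path[0] - 1], path[1:], sub)
    return (node[0], children[0], children[1])


def _within_caps(tree, cfg) -> bool:
    return _nodes(tree) <= cfg.max_nodes and _depth(tree) <= cfg.max_depth


def _linear_scale(t, y):
    """Optimal a + b*t fit; returns (a, b, rmse)."""
    tm = t.mean()
    tv = ((t - tm) ** 2).mean()
    if not np.isfinite(tv) or tv < 1e-12:
        a, b = float(y.mean()), 0.0
    else:
        b = float(((t - tm) * (y - y.mean())).mean() / tv)
        a = float(y.mean() - b * tm)
    resid = y - (a + b * t)
    return a, b, float(np.sqrt(np.mean(resid ** 2)))


def _fitness(tree, X, y, cfg):
    with np.errstate(all="ignore"):
        t = _eval(tree, X)
    if not np.all(np.isfinite(t)):
        return math.inf, (0.0, 0.0, math.inf)
    a, b, rmse = _linear_scale(t, y)
    # parsimony counts nodes of the folded expression (scaling included), so
    # an arbitrarily large weight collapses the champion to a constant
    n_eff = _nodes(_wrap_scaled(tree, a, b))
    return rmse + cfg.parsimony * n_eff, (a, b, rmse)


def _wrap_scaled(tree, a, b):
    if b == 0.0:
        return ("const", a)
    if a == 0.0 and b == 1.0:
        return tree
    return ("add", ("const", a), ("mul", ("const", b), tree))


def _constants(node, acc):
    if node[0] == "const":
        acc.append(float(node[1]))
    elif node[0] in _BINARY:
        _constants(node[1], acc)
        _constants(node[2], acc)
    return acc


def _substitute(node, values, pos):
    if node[0] == "const":
        v = values[pos[0]]
        pos[0] += 1
        return ("const", float(v))
    if node[0] in _BINARY:
        a = _substitute(node[1], values, pos)
        b = _substitute(node[2], values, pos)
        return (node[0], a, b)
    return node


def refit_constants(tree, X, y, max_nfev: int = 200):
    """Least-squares refit of every numeric constant in the tree."""
    c0 = _constants(tree, [])
    if not c0:
        return tree

    def resid(c):
        with np.errstate(all="ignore"):
            out = _eval(_substitute(tree, c, [0]), X) - y
        return np.where(np.isfinite(out), out, 1e6)

    sol = optimize.least_squares(resid, np.asarray(c0), method="trf",
                                 max_nfev=max_nfev)
    return _substitute(tree, sol.x, [0])


def _augment_with_variable(tree, X, y, cfg):
    """Best single-variable additive extension of ``tree``.

    Solves y ~ a + b*eval(tree) + c*x_j by least squares for each column and
    returns tree + (c/b)*x_j for the best j (so that the per-individual
    linear scaling reproduces the fitted model), or None if degenerate.
    """
    with np.errstate(all="ignore"):
        t = _eval(tree, X)
    if not np.all(np.isfinite(t)):
        return None
    best = None
    best_rmse = math.inf
    ones = np.ones_like(y)
    for j in range(X.shape[1]):
        A = np.column_stack([ones, t, X[:, j]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        if abs(coef[1]) < 1e-9:
            continue
        rmse = float(np.sqrt(np.mean((A @ coef - y) ** 2)))
        if rmse < best_rmse:
            best_rmse = rmse
            best = ("add", tree, ("mul", ("const", float(coef[2] / coef[1])),
                                  ("var", j)))
    return best


def evolve(X: np.ndarray, y: np.ndarray, config: SRConfig,
           columns: Optional[list[str]] = None,
           hof_size: int = 10) -> tuple[Expression, list[Expression]]:
    """Run the GP search; returns the champion plus a hall-of-fame list."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 20:
        raise ValidationError("evolve requires n >= 20")
    if columns is None:
        columns = [f"x{j}" for j in range(X.shape[1])]
    p = X.shape[1]
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # ramped half-and-half initialization
    pop = []
    for i in range(cfg.population):
        d = 2 + i % max(1, min(4, cfg.max_depth - 1))
        t = _random_tree(rng, p, d, full=(i % 2 == 0))
        while not _within_caps(t, cfg):
            t = _random_tree(rng, p, 2, full=False)
        pop.append(t)

    fits = [_fitness(t, X, y, cfg) for t in pop]
    best_idx = int(np.argmin([f[0] for f in fits]))
    best_tree, best_fit = pop[best_idx], fits[best_idx][0]
    hof: dict[str, tuple[float, tuple]] = {}

    def record(tree, fit):
        key = _prefix(tree)
        if key not in hof or fit < hof[key][0]:
            hof[key] = (fit, tree)

    record(best_tree, best_fit)
    since_improved = 0

    def tournament():
        idx = rng.integers(len(pop), size=cfg.tournament)
        wi = min(idx, key=lambda i: fits[i][0])
        return pop[wi]

    for _ in range(cfg.generations):
        newpop = [best_tree]  # elitism: champion survives unchanged
        while len(newpop) < cfg.population:
            r = rng.random()
            if r < cfg.p_crossover:
                p1, p2 = tournament(), tournament()
                n1 = list(_all_nodes(p1))
                n2 = list(_all_nodes(p2))
                path1 = n1[int(rng.integers(len(n1)))][0]
                sub = n2[int(rng.integers(len(n2)))][1]
                child = _replace(p1, path1, sub)
                if not _within_caps(child, cfg):
                    child = p1
            elif r < cfg.p_crossover + cfg.p_subtree_mutation:
                p1 = tournament()
                n1 = list(_all_nodes(p1))
                path1 = n1[int(rng.integers(len(n1)))][0]
                sub = _random_tree(rng, p, 3, full=False)
                child = _replace(p1, path1, sub)
                if not _within_caps(child, cfg):
                    child = p1
            elif r < (cfg.p_crossover + cfg.p_subtree_mutation
                      + cfg.p_insert_mutation):
                # insertion: graft a node into a fresh binary op so additive
                # terms can be appended anywhere, including at the root
                p1 = tournament()
                n1 = list(_all_nodes(p1))
                path1 = n1[int(rng.integers(len(n1)))][0]
                old = n1[[q[0] for q in n1].index(path1)][1]
                op = _BINARY[int(rng.integers(len(_BINARY)))]
                leaf = _random_tree(rng, p, 2, full=False)
                wrapped = (op, old, leaf) if rng.random() < 0.5 \
                    else (op, leaf, old)
                child = _replace(p1, path1, wrapped)
                if not _within_caps(child, cfg):
                    child = p1
            elif r < (cfg.p_crossover + cfg.p_subtree_mutation
                      + cfg.p_insert_mutation + cfg.p_const_mutation):
                p1 = tournament()
                consts = _constants(p1, [])
                if consts:
                    jitter = [c + rng.normal(0, 0.3) for c in consts]
                    child = _substitute(p1, jitter, [0])
                else:
                    child = p1
            else:
                child = tournament()
            newpop.append(child)
        pop = newpop
        fits = [_fitness(t, X, y, cfg) for t in pop]
        # local search: constant refit of the few best distinct individuals
        order = np.argsort([f[0] for f in fits], kind="stable")
        seen = set()
        for gi in order.tolist():
            key = _prefix(pop[gi])
            if key in seen:
                continue
            seen.add(key)
            if len(seen) > 5:
                break
            cand = refit_constants(_wrap_scaled(pop[gi], *fits[gi][1][:2]),
                                   X, y, max_nfev=40)
            cand_fit, cand_aux = _fitness(cand, X, y, cfg)
            if cand_fit < fits[gi][0] and _within_caps(cand, cfg):
                pop[gi] = cand
                fits[gi] = (cand_fit, cand_aux)
        # memetic step: greedily chain additive variable terms (closed-form
        # LS coefficients) onto the champion, then inject the result into the
        # population in place of the worst individual; ordinary selection
        # decides whether the extended form survives the parsimony pressure
        order = np.argsort([f[0] for f in fits], kind="stable")
        cand = pop[order[0]]
        cand_rmse = fits[order[0]][1][2]
        improved = False
        for _ in range(3):
            aug = _augment_with_variable(cand, X, y, cfg)
            if aug is None or not _within_caps(aug, cfg):
                break
            _, (_, _, aug_rmse) = _fitness(aug, X, y, cfg)
            if aug_rmse < cand_rmse - 1e-9:
                cand, cand_rmse, improved = aug, aug_rmse, True
            else:
                break
        if improved:
            wi = int(order[-1])
            pop[wi] = cand
            fits[wi] = _fitness(cand, X, y, cfg)
        gi = int(np.argmin([f[0] for f in fits]))
        if fits[gi][0] < best_fit - 1e-12:
            best_fit, best_tree = fits[gi][0], pop[gi]
            since_improved = 0
        else:
            since_improved += 1
        record(pop[gi], fits[gi][0])
        if since_improved >= cfg.stagnation:
            # diversity restart: re-randomize the worst half of the population
            order = np.argsort([f[0] for f in fits], kind="stable")
            for wi in order[len(pop) // 2:].tolist():
                d = 2 + int(rng.integers(max(1, min(4, cfg.max_depth - 1))))
                t = _random_tree(rng, p, d, full=bool(rng.integers(2)))
                while not _within_caps(t, cfg):
                    t = _random_tree(rng, p, 2, full=False)
                pop[wi] = t
                fits[wi] = _fitness(t, X, y, cfg)
            since_improved = 0

    # final: fold linear scaling into the champion and refit all constants
    fit0, (a, b, _) = _fitness(best_tree, X, y, cfg)
    final_tree = refit_constants(_wrap_scaled(best_tree, a, b), X, y)
    with np.errstate(all="ignore"):
        resid = _eval(final_tree, X) - y
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    champion = Expression(final_tree, list(columns),
                          rmse + cfg.parsimony * _nodes(final_tree), rmse)

    shortlist = sorted(hof.values(), key=lambda kv: kv[0])[:hof_size]
    hof_exprs = [Expression(t, list(columns), f) for f, t in shortlist]
    return champion, hof_exprs


def evaluate(expr: Expression, X: np.ndarray) -> np.ndarray:
    return expr.evaluate(X)


def complexity(expr: Expression) -> tuple[int, int]:
    return expr.complexity()
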