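"""Model specification: subject tables, filters, formulas and design matrices.

A model is declared as an R-style formula string, ``"FDG ~ VBM + AGE +
GENDER"``, plus a role for every symbol: ``scalar`` (one number per
subject), ``factor`` (categorical, dummy-coded), or ``voxelwise`` (one 3D
image per subject, so the design matrix differs at every voxel). ``a*b``
expands to main effects plus interaction; ``a:b`` is the bare product term.
Any variable may carry an ordered list of arithmetic operations (negate,
inverse, add c, multiply c) applied before fitting.

Sample filtering uses a deliberately small boolean mini-grammar
(comparisons on columns, ``& | !`` and parentheses) rather than evaluating
arbitrary host-language strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volio import VoxelMatrix

__all__ = [
    "VariableOp",
    "VariableSpec",
    "ModelSpec",
    "FilterError",
    "apply_filter",
    "parse_model",
    "apply_variable_op",
    "apply_ops",
    "DesignBuilder",
    "realize_design",
    "load_table",
]

ROLES = ("scalar", "factor", "voxelwise")
FAMILIES = ("gaussian", "binomial", "poisson", "gamma", "inverse_gaussian")


@dataclass(frozen=True)
class VariableOp:
    """One arithmetic operation: ``negate``, ``inverse``, ``add`` or ``multiply``."""

    kind: str
    value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("negate", "inverse", "add", "multiply"):
            raise ValueError(f"unknown variable operation {self.kind!r}")
        if self.kind in ("add", "multiply") and self.value is None:
            raise ValueError(f"operation {self.kind!r} requires a constant")


@dataclass(frozen=True)
class VariableSpec:
    name: str
    role: str
    ops: tuple[VariableOp, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.ops and self.role == "factor":
            raise ValueError(f"arithmetic operations cannot apply to factor {self.name!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Parsed model: response, ordered terms, family, optional grouping factor.

    ``terms`` are tuples of variable names: length-1 for main effects,
    longer for interactions (realized as elementwise products). The
    intercept is implicit and always first in the design.
    """

    response: VariableSpec
    terms: tuple[tuple[str, ...], ...]
    variables: dict[str, VariableSpec]
    family: str = "gaussian"
    grouping: str | None = None

    @property
    def has_voxelwise_terms(self) -> bool:
        return any(
            self.variables[name].role == "voxelwise" for t in self.terms for name in t
        )

    @property
    def voxelwise_names(self) -> list[str]:
        names = [v.name for v in self.variables.values() if v.role == "voxelwise"]
        return names


# ---------------------------------------------------------------------------
# sample filter mini-grammar
# ---------------------------------------------------------------------------

class FilterError(ValueError):
    """Syntax or semantic error in a sample-filter expression."""


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<cmp>==|!=|<=|>=|<|>)
      | (?P<and>&)
      | (?P<or>\|)
      | (?P<not>!)
      | (?P<lpar>\()
      | (?P<rpar>\))
      | (?P<num>-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)
      | (?P<str>'[^']*'|"[^"]*")
      | (?P<ident>[A-Za-z_][A-Za-z0-9_.]*)
    )""",
    re.VERBOSE,
)


def _tokenize_filter(expr: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise FilterError(f"filter syntax error at position {pos}: {expr[pos:]!r}")
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _FilterParser:
    """Recursive-descent parser/evaluator for the boolean filter grammar."""

    def __init__(self, expr: str, table: pd.DataFrame):
        self.expr = expr
        self.tokens = _tokenize_filter(expr)
        self.i = 0
        self.table = table

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.expr))

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise FilterError("empty filter expression")
        result = self._or()
        if self.i < len(self.tokens):
            kind, val, pos = self._peek()
            raise FilterError(f"unexpected token {val!r} at position {pos}")
        if result.dtype != bool:
            raise FilterError("filter expression is not purely boolean")
        return result

    def _or(self) -> np.ndarray:
        left = self._and()
        while self._peek()[0] == "or":
            self._next()
            left = left | self._and()
        return left

    def _and(self) -> np.ndarray:
        left = self._not()
        while self._peek()[0] == "and":
            self._next()
            left = left & self._not()
        return left

    def _not(self) -> np.ndarray:
        if self._peek()[0] == "not":
            self._next()
            return ~self._not()
        return self._primary()

    def _primary(self) -> np.ndarray:
        kind, val, pos = self._peek()
        if kind == "lpar":
            self._next()
            inner = self._or()
            if self._peek()[0] != "rpar":
                raise FilterError(f"missing ')' at position {self._peek()[2]}")
            self._next()
            return inner
        return self._comparison()

    def _operand(self):
        kind, val, pos = self._next()
        if kind == "num":
            return float(val)
        if kind == "str":
            return val[1:-1]
        if kind == "ident":
            if val not in self.table.columns:
                raise FilterError(f"unknown column {val}")
            return self.table[val]
        raise FilterError(f"expected a column, number or string at position {pos}")

    def _comparison(self) -> np.ndarray:
        left = self._operand()
        kind, op, pos = self._next()
        if kind != "cmp":
            raise FilterError(f"expected a comparison operator at position {pos}")
        right = self._operand()
        funcs = {
            "==": lambda a, b: a == b,
            "!=": lambda a, b: a != b,
            "<": lambda a, b: a < b,
            "<=": lambda a, b: a <= b,
            ">": lambda a, b: a > b,
            ">=": lambda a, b: a >= b,
        }
        out = funcs[op](left, right)
        if np.isscalar(out) or isinstance(out, (bool, np.bool_)):
            out = np.full(len(self.table), bool(out))
        return np.asarray(out, dtype=bool)


def apply_filter(table: pd.DataFrame, expr: str | None) -> pd.DataFrame:
    """Return the row subset where ``expr`` is true; original order preserved.

    ``expr`` is a boolean combination of column comparisons, e.g.
    ``"AGE > 65 & (DX == 'MCI' | DX == 'AD')"``. ``None`` or blank keeps
    every row.
    """
    if expr is None or expr.strip() == "":
        return table
    keep = _FilterParser(expr, table).parse()
    return table.loc[np.asarray(keep)]


# ---------------------------------------------------------------------------
# formula parsing
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


def _as_varspec(name: str, decl) -> VariableSpec:
    if isinstance(decl, VariableSpec):
        return decl
    if isinstance(decl, str):
        return VariableSpec(name=name, role=decl)
    raise TypeError(f"role for {name!r} must be a string or VariableSpec")


def parse_model(
    formula: str,
    roles: dict[str, str | VariableSpec],
    family: str = "gaussian",
    grouping: str | None = None,
) -> ModelSpec:
    """Parse ``"response ~ t1 + t2 + a*b"`` with declared variable roles.

    ``a*b`` expands to ``a + b + a:b`` (constituents auto-added if absent);
    ``a:b`` adds only the product term. The intercept is implicit.
    Coefficients are ordered intercept-first then terms in formula order,
    with factors dummy-coded at design time.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    if "~" not in formula:
        raise ValueError(f"formula must contain '~': {formula!r}")
    lhs, rhs = formula.split("~", 1)
    lhs = lhs.strip()
    if not _NAME_RE.match(lhs):
        raise ValueError(f"invalid response name {lhs!r}")
    if lhs not in roles:
        raise ValueError(f"undeclared symbol {lhs!r}: every variable needs a role")
    if rhs.strip() == "":
        raise ValueError("empty model right-hand side")

    terms: list[tuple[str, ...]] = []

    def add(term: tuple[str, ...]) -> None:
        if term not in terms:
            terms.append(term)

    for raw in rhs.split("+"):
        raw = raw.strip()
        if raw == "":
            raise ValueError(f"empty term in formula {formula!r}")
        if raw == "1":
            continue  # intercept is implicit anyway
        if "*" in raw:
            parts = tuple(p.strip() for p in raw.split("*"))
            for p in parts:
                add((p,))
            add(parts)
        elif ":" in raw:
            add(tuple(p.strip() for p in raw.split(":")))
        else:
            add((raw,))

    variables: dict[str, VariableSpec] = {lhs: _as_varspec(lhs, roles[lhs])}
    for term in terms:
        for name in term:
            if not _NAME_RE.match(name):
                raise ValueError(f"invalid variable name {name!r}")
            if name not in roles:
                raise ValueError(f"undeclared symbol {name!r}: every variable needs a role")
            variables.setdefault(name, _as_varspec(name, roles[name]))
    if grouping is not None:
        if grouping not in roles:
            raise ValueError(f"undeclared grouping factor {grouping!r}")
        variables.setdefault(grouping, _as_varspec(grouping, roles[grouping]))

    response = variables[lhs]
    if response.role == "voxelwise" and family == "binomial":
        raise ValueError(
            "voxel-wise response with family=binomial is not supported: "
            "a binary response cannot be an image"
        )
    return ModelSpec(
        response=response,
        terms=tuple(terms),
        variables=variables,
        family=family,
        grouping=grouping,
    )


# ---------------------------------------------------------------------------
# variable operations
# ---------------------------------------------------------------------------

def apply_variable_op(data, op: VariableOp):
    """Apply one arithmetic operation elementwise; shape and geometry unchanged."""
    if isinstance(data, VoxelMatrix):
        return VoxelMatrix(
            data=apply_variable_op(data.data, op),
            geometry=data.geometry,
            subject_ids=list(data.subject_ids),
        )
    arr = np.asarray(data, dtype=float)
    if op.kind == "negate":
        return -arr
    if op.kind == "inverse":
        n_zero = int(np.count_nonzero(arr == 0))
        if n_zero:
            raise ValueError(
                f"inverse operation undefined: {n_zero} zero value(s) in the data"
            )
        return 1.0 / arr
    if op.kind == "add":
        return arr + op.value
    return arr * op.value


def apply_ops(data, ops) -> np.ndarray:
    """Apply an ordered sequence of operations (declaration order)."""
    for op in ops:
        data = apply_variable_op(data, op)
    return data


# ---------------------------------------------------------------------------
# design realization
# ---------------------------------------------------------------------------

def _dummy_code(series: pd.Series, name: str, reference: str | None = None):
    """Treatment coding: k-level factor -> k-1 indicator columns.

    Reference level is the lexicographically first unless given.
    """
    levels = sorted(map(str, pd.unique(series.astype(str))))
    if len(levels) < 2:
        raise ValueError(f"factor {name!r} has a single level {levels!r}")
    if reference is None:
        reference = levels[0]
    elif reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels} for {name!r}")
    coded = []
    names = []
    vals = series.astype(str).to_numpy()
    for lev in levels:
        if lev == reference:
            continue
        coded.append((vals == lev).astype(float))
        names.append(f"{name}[{lev}]")
    return np.column_stack(coded), names


class DesignBuilder:
    """Realizes per-voxel design matrices and responses for a ModelSpec.

    Variable operations are applied once at construction. Columns deriving
    only from scalar covariates and factors are built once and shared; at
    voxel ``j`` only the columns involving voxel-wise variables change.
    """

    def __init__(
        self,
        spec: ModelSpec,
        table: pd.DataFrame,
        voxel_data: dict[str, VoxelMatrix] | None = None,
        factor_references: dict[str, str] | None = None,
    ):
        self.spec = spec
        self.table = table.reset_index(drop=True)
        self.n = len(self.table)
        if self.n == 0:
            raise ValueError("0 samples after filter")
        voxel_data = voxel_data or {}
        factor_references = factor_references or {}

        # realized per-variable data blocks
        self._scalar: dict[str, np.ndarray] = {}       # name -> (n,)
        self._factor: dict[str, tuple[np.ndarray, list[str]]] = {}
        self._voxel: dict[str, np.ndarray] = {}        # name -> (n, tau)
        self.tau: int | None = None

        for name, var in spec.variables.items():
            if var.role == "voxelwise":
                if name not in voxel_data:
                    raise ValueError(f"no voxel data supplied for voxel-wise variable {name!r}")
                vm = voxel_data[name]
                if vm.n_subjects != self.n:
                    raise ValueError(
                        f"voxel-wise variable {name!r} has {vm.n_subjects} subjects, "
                        f"table has {self.n}"
                    )
                self._voxel[name] = np.asarray(apply_ops(vm.data, var.ops), dtype=float)
                if self.tau is None:
                    self.tau = vm.tau
                elif vm.tau != self.tau:
                    raise ValueError("voxel-wise variables disagree on mask size")
            elif var.role == "factor":
                if name not in self.table.columns:
                    raise ValueError(f"unknown column {name}")
                self._factor[name] = _dummy_code(
                    self.table[name], name, factor_references.get(name)
                )
            else:
                if name not in self.table.columns:
                    raise ValueError(f"unknown column {name}")
                col = self.table[name].to_numpy(dtype=float)
                self._scalar[name] = np.asarray(apply_ops(col, var.ops), dtype=float)

        # column layout: intercept, then each term's block in formula order
        self.column_names: list[str] = ["Intercept"]
        self._term_slices: list[slice] = []
        self._term_is_voxelwise: list[bool] = []
        start = 1
        for term in spec.terms:
            block_names = self._term_names(term)
            self.column_names.extend(block_names)
            self._term_slices.append(slice(start, start + len(block_names)))
            self._term_is_voxelwise.append(
                any(spec.variables[v].role == "voxelwise" for v in term)
            )
            start += len(block_names)
        self.p = start
        self.has_voxelwise = any(self._term_is_voxelwise)
        self.voxelwise_response = spec.response.role == "voxelwise"
        if self.voxelwise_response or self.has_voxelwise:
            if self.tau is None:
                raise ValueError("model names voxel-wise variables but none were supplied")

        self._static = self._build(None)

    # -- helpers ---------------------------------------------------------
    def _term_names(self, term: tuple[str, ...]) -> list[str]:
        parts: list[list[str]] = []
        for v in term:
            if self.spec.variables[v].role == "factor":
                parts.append(self._factor[v][1])
            else:
                parts.append([v])
        names = parts[0]
        for extra in parts[1:]:
            names = [f"{a}:{b}" for a in names for b in extra]
        return names

    def _var_columns(self, name: str, j: int | None) -> np.ndarray:
        var = self.spec.variables[name]
        if var.role == "factor":
            return self._factor[name][0]
        if var.role == "voxelwise":
            if j is None:
                return np.zeros((self.n, 1))  # placeholder in the static skeleton
            return self._voxel[name][:, j][:, None]
        return self._scalar[name][:, None]

    def _term_block(self, term: tuple[str, ...], j: int | None) -> np.ndarray:
        block = self._var_columns(term[0], j)
        for v in term[1:]:
            nxt = self._var_columns(v, j)
            # interaction block: all pairwise column products
            block = np.concatenate(
                [block[:, [a]] * nxt for a in range(block.shape[1])], axis=1
            )
        return block

    def _build(self, j: int | None) -> np.ndarray:
        X = np.empty((self.n, self.p), dtype=np.float64)
        X[:, 0] = 1.0
        for term, sl in zip(self.spec.terms, self._term_slices):
            X[:, sl] = self._term_block(term, j)
        return X

    # -- public API ------------------------------------------------------
    def design(self, j: int | None = None) -> np.ndarray:
        """Design matrix at voxel ``j`` (any ``j`` gives the same matrix for
        purely scalar models; those may pass ``None``)."""
        if not self.has_voxelwise:
            return self._static
        if j is None:
            raise ValueError("model has voxel-wise terms: a voxel index is required")
        X = self._static.copy()
        for term, sl, isvox in zip(
            self.spec.terms, self._term_slices, self._term_is_voxelwise
        ):
            if isvox:
                X[:, sl] = self._term_block(term, j)
        return X

    def response(self, j: int | None = None) -> np.ndarray:
        var = self.spec.response
        if var.role == "voxelwise":
            if j is None:
                raise ValueError("voxel-wise response: a voxel index is required")
            return self._voxel[var.name][:, j]
        if var.role == "factor":
            raise ValueError("a factor cannot be the model response")
        if var.name not in self._scalar:
            col = self.table[var.name].to_numpy(dtype=float)
            self._scalar[var.name] = np.asarray(apply_ops(col, var.ops), dtype=float)
        return self._scalar[var.name]

    def response_matrix(self) -> np.ndarray:
        """Full ``n x tau`` response for voxel-wise-response models."""
        if not self.voxelwise_response:
            raise ValueError("response is scalar")
        return self._voxel[self.spec.response.name]

    def group_codes(self) -> np.ndarray:
        """Integer group codes for the spec's grouping factor (mixed models)."""
        if self.spec.grouping is None:
            raise ValueError("model has no grouping factor")
        col = self.table[self.spec.grouping].astype(str)
        _, codes = np.unique(col.to_numpy(), return_inverse=True)
        return codes


def realize_design(
    spec: ModelSpec,
    table: pd.DataFrame,
    voxel_data: dict[str, VoxelMatrix] | None,
    j: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One-shot design realization at voxel ``j``: ``(X, y, column_names)``."""
    b = DesignBuilder(spec, table, voxel_data)
    return b.design(j), b.response(j), b.column_names


def load_table(path, id_column: str | None = None) -> pd.DataFrame:
    """Load a subject table from CSV; checks id uniqueness when given."""
    table = pd.read_csv(path)
    if id_column is not None:
        if id_column not in table.columns:
            raise ValueError(f"unknown column {id_column}")
        if table[id_column].duplicated().any():
            dupes = table[id_column][table[id_column].duplicated()].tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
    return table
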