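"""Declarative latent-variable model specification and its text DSL.

The DSL follows the conventions common to covariance-structure software:

``F =~ x1 + x2 + x3``
    ``F`` is a latent factor measured by the indicators on the right.
``y ~ x1 + x2``
    ``y`` is regressed on the predictors on the right.
``a ~~ b``
    free covariance between the (residuals of) ``a`` and ``b``; ``a ~~ a``
    addresses a variance.

A right-hand term may carry a premultiplier: a numeric literal fixes the
parameter (``0*x`` drops a path, ``1*x`` is a marker loading), an
identifier attaches a label, and repeated labels impose equality
constraints.  ``#`` starts a comment.  Parsing round-trips: serializing a
parsed spec and re-parsing yields an identical specification.

Expansion to a full parameter table adds the conventional defaults:
residual variances for every observed variable, variances/covariances for
every exogenous variable, free disturbance covariances between latent
factors, and the chosen identification (latent variances fixed to one, or
first loadings fixed as markers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Parameter",
    "ModelSpec",
    "ModelSpecError",
    "parse_model_spec",
]


class ModelSpecError(ValueError):
    """Raised for malformed or inconsistent model specifications."""


#: parameter kinds
LOADING = "loading"
REGRESSION = "regression"
COVARIANCE = "covariance"
VARIANCE = "variance"


@dataclass(frozen=True)
class Parameter:
    """One entry of a model's parameter table.

    ``lhs``/``rhs`` follow the DSL reading order: for loadings lhs is the
    factor and rhs the indicator; for regressions lhs is the outcome; for
    (co)variances the pair is stored in sorted order.
    """

    kind: str
    lhs: str
    rhs: str
    free: bool = True
    value: float | None = None  # fixed value, or start value hint for free params
    label: str | None = None

    @property
    def name(self) -> str:
        if self.kind == LOADING:
            return f"{self.lhs}=~{self.rhs}"
        if self.kind == REGRESSION:
            return f"{self.lhs}~{self.rhs}"
        return f"{self.lhs}~~{self.rhs}"

    def key(self) -> tuple[str, str, str]:
        return (self.kind, self.lhs, self.rhs)


_TERM_RE = re.compile(
    r"^\s*(?:(?P<mult>[A-Za-z_][A-Za-z_0-9.]*|[-+]?\d+(?:\.\d*)?(?:[eE][-+]?\d+)?)\s*\*\s*)?"
    r"(?P<var>[A-Za-z_][A-Za-z_0-9.]*)\s*$"
)

_OPS = ("=~", "~~", "~")  # order matters: match =~ and ~~ before ~


def _split_line(line: str) -> tuple[str, str, str] | None:
    code = line.split("#", 1)[0].strip()
    if not code:
        return None
    for op in _OPS:
        # scan for operator not part of a longer operator
        idx = code.find(op)
        if op == "~":
            # make sure we did not hit "=~"/"~~" handled above
            while idx > 0 and code[idx - 1] == "=":
                idx = code.find("~", idx + 1)
            if idx != -1 and idx + 1 < len(code) and code[idx + 1] == "~":
                idx = -1
        if idx != -1:
            return code[:idx].strip(), op, code[idx + len(op):].strip()
    raise ModelSpecError(f"no operator found in line: {line!r}")


def _parse_terms(text: str, lineno: int) -> list[tuple[str, float | None, str | None]]:
    terms = []
    for raw in text.split("+"):
        m = _TERM_RE.match(raw)
        if not m:
            raise ModelSpecError(f"line {lineno}: cannot parse term {raw.strip()!r}")
        mult = m.group("mult")
        fixed: float | None = None
        label: str | None = None
        if mult is not None:
            try:
                fixed = float(mult)
            except ValueError:
                label = mult
        terms.append((m.group("var"), fixed, label))
    return terms


@dataclass
class ModelSpec:
    """A parsed latent-variable model: explicit parameters plus name sets."""

    parameters: list[Parameter] = field(default_factory=list)
    latent_factors: list[str] = field(default_factory=list)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_text(cls, text: str) -> "ModelSpec":
        params: list[Parameter] = []
        latents: list[str] = []
        seen: set[tuple[str, str, str]] = set()
        for lineno, line in enumerate(text.splitlines(), start=1):
            split = _split_line(line)
            if split is None:
                continue
            lhs, op, rhs = split
            if not re.match(r"^[A-Za-z_][A-Za-z_0-9.]*$", lhs):
                raise ModelSpecError(f"line {lineno}: bad left-hand name {lhs!r}")
            for var, fixed, label in _parse_terms(rhs, lineno):
                if op == "=~":
                    kind, a, b = LOADING, lhs, var
                    if lhs not in latents:
                        latents.append(lhs)
                elif op == "~":
                    kind, a, b = REGRESSION, lhs, var
                else:
                    kind, a, b = COVARIANCE, *sorted((lhs, var))
                    if a == b:
                        kind = VARIANCE
                p = Parameter(kind, a, b, free=fixed is None, value=fixed, label=label)
                if p.key() in seen:
                    raise ModelSpecError(f"line {lineno}: duplicate parameter {p.name}")
                seen.add(p.key())
                params.append(p)
        spec = cls(parameters=params, latent_factors=latents)
        spec.validate()
        return spec

    # -- views ------------------------------------------------------------
    @property
    def loadings(self) -> list[Parameter]:
        return [p for p in self.parameters if p.kind == LOADING]

    @property
    def regressions(self) -> list[Parameter]:
        return [p for p in self.parameters if p.kind == REGRESSION]

    @property
    def observed_vars(self) -> list[str]:
        """Observed variables in first-appearance order."""
        latent = set(self.latent_factors)
        out: list[str] = []
        for p in self.parameters:
            for v in (p.rhs, p.lhs) if p.kind == LOADING else (p.lhs, p.rhs):
                if v not in latent and v not in out:
                    out.append(v)
        return out

    @property
    def all_vars(self) -> list[str]:
        return self.observed_vars + list(self.latent_factors)

    def indicators_of(self, factor: str) -> list[str]:
        return [p.rhs for p in self.loadings if p.lhs == factor]

    # -- checks -----------------------------------------------------------
    def validate(self) -> None:
        latent = set(self.latent_factors)
        for f in latent:
            if not self.indicators_of(f):
                raise ModelSpecError(f"latent factor {f} has no indicators")
        # regression cycle check over the directed graph of ~ paths
        edges: dict[str, set[str]] = {}
        for p in self.regressions:
            edges.setdefault(p.rhs, set()).add(p.lhs)
        color: dict[str, int] = {}

        def visit(node: str, stack: tuple[str, ...]) -> None:
            if color.get(node) == 1:
                raise ModelSpecError(f"cyclic regression involving {' -> '.join(stack + (node,))}")
            if color.get(node) == 2:
                return
            color[node] = 1
            for nxt in edges.get(node, ()):
                visit(nxt, stack + (node,))
            color[node] = 2

        for node in list(edges):
            if color.get(node) != 2:
                visit(node, ())
        # labels must not mix variances with non-variances (different
        # optimizer parameterizations)
        by_label: dict[str, set[str]] = {}
        for p in self.parameters:
            if p.label:
                by_label.setdefault(p.label, set()).add(p.kind)
        for lab, kinds in by_label.items():
            if VARIANCE in kinds and len(kinds) > 1:
                raise ModelSpecError(f"label {lab} mixes variance and non-variance parameters")

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        lines = []
        for p in self.parameters:
            if p.kind == LOADING:
                lhs, op, rhs = p.lhs, "=~", p.rhs
            elif p.kind == REGRESSION:
                lhs, op, rhs = p.lhs, "~", p.rhs
            else:
                lhs, op, rhs = p.lhs, "~~", p.rhs
            prefix = ""
            if not p.free:
                prefix = f"{p.value:g}*"
            elif p.label:
                prefix = f"{p.label}*"
            lines.append(f"{lhs} {op} {prefix}{rhs}")
        return "\n".join(lines) + "\n"

    # -- editing helpers (used by the model ladder) -----------------------
    def with_parameters(self, extra: Iterable[Parameter]) -> "ModelSpec":
        extra = list(extra)
        seen = {p.key() for p in self.parameters}
        for p in extra:
            if p.key() in seen:
                raise ModelSpecError(f"parameter {p.name} already present")
        latents = list(self.latent_factors)
        for p in extra:
            if p.kind == LOADING and p.lhs not in latents:
                latents.append(p.lhs)
        return ModelSpec(parameters=self.parameters + extra, latent_factors=latents)

    def fix_parameters(self, keys: Iterable[tuple[str, str, str]], value: float = 0.0) -> "ModelSpec":
        """Return a copy with the addressed parameters fixed to ``value``."""
        keys = set(keys)
        new = []
        hit = set()
        for p in self.parameters:
            if p.key() in keys:
                new.append(replace(p, free=False, value=value, label=None))
                hit.add(p.key())
            else:
                new.append(p)
        missing = keys - hit
        if missing:
            raise ModelSpecError(f"cannot fix unknown parameters: {sorted(missing)}")
        return ModelSpec(parameters=new, latent_factors=list(self.latent_factors))

    def label_parameters(self, keys: Sequence[tuple[str, str, str]], label: str) -> "ModelSpec":
        """Return a copy with one shared label (equality constraint) on ``keys``."""
        keys = set(keys)
        new = []
        hit = set()
        for p in self.parameters:
            if p.key() in keys:
                if not p.free:
                    raise ModelSpecError(f"cannot label fixed parameter {p.name}")
                new.append(replace(p, label=label))
                hit.add(p.key())
            else:
                new.append(p)
        missing = keys - hit
        if missing:
            raise ModelSpecError(f"cannot label unknown parameters: {sorted(missing)}")
        return ModelSpec(parameters=new, latent_factors=list(self.latent_factors))

    # -- expansion --------------------------------------------------------
    def parameter_table(self, identification: str = "unit_variance") -> list[Parameter]:
        """Full parameter table with conventional defaults added.

        Rules: every observed variable gets a (residual) variance; every
        latent factor gets a variance -- fixed to 1 under ``unit_variance``
        (also for disturbances of endogenous factors), or free with the
        first loading fixed to 1 under ``marker``; covariances are freed by
        default between all pairs of latent factors (their disturbances)
        and between all pairs of exogenous observed variables.
        """
        if identification not in ("unit_variance", "marker"):
            raise ModelSpecError(f"unknown identification {identification!r}")
        table = list(self.parameters)
        keys = {p.key() for p in table}

        def add(p: Parameter) -> None:
            if p.key() not in keys:
                table.append(p)
                keys.add(p.key())

        latent = set(self.latent_factors)
        observed = self.observed_vars
        outcome_of_regression = {p.lhs for p in self.regressions}
        indicator = {p.rhs for p in self.loadings if p.rhs not in latent}
        exo_observed = [v for v in observed if v not in indicator and v not in outcome_of_regression]

        if identification == "marker":
            first_loading: dict[str, Parameter] = {}
            for p in self.parameters:
                if p.kind == LOADING and p.lhs not in first_loading:
                    first_loading[p.lhs] = p
            table = [
                replace(p, free=False, value=1.0, label=None)
                if p.key() in {q.key() for q in first_loading.values()} and p.free
                else p
                for p in table
            ]

        # variances
        for v in observed:
            add(Parameter(VARIANCE, v, v, free=True))
        for f in self.latent_factors:
            if identification == "unit_variance":
                add(Parameter(VARIANCE, f, f, free=False, value=1.0))
            else:
                add(Parameter(VARIANCE, f, f, free=True))

        # default covariances: latent-latent (disturbances) and exogenous
        # observed pairs
        for i, a in enumerate(self.latent_factors):
            for b in self.latent_factors[i + 1:]:
                # second-order structure: factors that are indicators of a
                # higher-order factor do not get free mutual covariances
                if any(p.kind == LOADING and p.rhs in (a, b) and p.lhs in latent for p in self.parameters):
                    continue
                x, y = sorted((a, b))
                add(Parameter(COVARIANCE, x, y, free=True))
        for i, a in enumerate(exo_observed):
            for b in exo_observed[i + 1:]:
                x, y = sorted((a, b))
                add(Parameter(COVARIANCE, x, y, free=True))
        return table


def parse_model_spec(text: str) -> ModelSpec:
    """Parse DSL text into a :class:`ModelSpec` (round-trips via ``to_text``)."""
    return ModelSpec.from_text(text)
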