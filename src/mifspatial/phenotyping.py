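"""Multi-marker phenotype gating.

Each cell receives exactly one leaf phenotype from an ordered list of boolean
marker rules; cells matching no rule fall back to ``"other"`` (macrophages,
mast cells, neutrophils, dendritic cells, ... are not separately resolved by
the panel). Rule order encodes biological precedence so leaf classes are
disjoint: within CD8+ T cells the terminally dysfunctional state (Tim3+)
dominates the predysfunctional one (PD-1+ or CD103+); pan-CK (epithelial)
dominates stromal markers; CD31 (endothelium) dominates aSMA (fibroblast).

Aggregate populations (e.g. total CD8+ T cells regardless of functional
state) are expressed as *groups*: named unions of leaf labels, resolved via
:meth:`PhenotypeScheme.resolve`.

Rule expressions use a small boolean grammar over marker names::

    CD8 & (PD1 | CD103) & !TIM3

with ``&``/``|``/``!`` (or ``~``) and parentheses.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import yaml

from .io_cells import PANEL_MARKERS, TissueSite

FALLBACK_LABEL = "other"


class SchemeError(ValueError):
    """A phenotype scheme is malformed or incompatible with a site."""


# ---------------------------------------------------------------------------
# expression grammar
# ---------------------------------------------------------------------------

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp, ast.BitAnd, ast.BitOr,
    ast.UnaryOp, ast.Invert,
    ast.Name, ast.Load,
)


def compile_expression(text: str):
    """Compile a marker expression to (code object, referenced marker names)."""
    src = text.replace("!", "~")
    try:
        tree = ast.parse(src, mode="eval")
    except SyntaxError as exc:
        raise SchemeError(f"cannot parse marker expression {text!r}: {exc}") from None
    names: set[str] = set()
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise SchemeError(
                f"disallowed construct {type(node).__name__} in expression {text!r}"
            )
        if isinstance(node, ast.Name):
            names.add(node.id)
    return compile(tree, "<marker-expression>", "eval"), frozenset(names)


def evaluate_expression(code, env: Mapping[str, np.ndarray]) -> np.ndarray:
    """Evaluate a compiled expression on boolean marker arrays."""
    return np.asarray(eval(code, {"__builtins__": {}}, dict(env)), dtype=bool)


# ---------------------------------------------------------------------------
# scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeRule:
    """One gating rule: first matching rule in priority order wins."""

    label: str
    expression: str
    priority: int
    compartment: str = "any"  # tumor | stroma | any

    def __post_init__(self) -> None:
        if self.compartment not in ("tumor", "stroma", "any"):
            raise SchemeError(f"bad compartment constraint {self.compartment!r}")
        code, names = compile_expression(self.expression)
        object.__setattr__(self, "_code", code)
        object.__setattr__(self, "_names", names)

    @property
    def marker_names(self) -> frozenset:
        return self._names  # type: ignore[attr-defined]

    def mask(self, env: Mapping[str, np.ndarray]) -> np.ndarray:
        return evaluate_expression(self._code, env)  # type: ignore[attr-defined]


@dataclass(frozen=True)
class PhenotypeScheme:
    """Ordered gating rules plus named groups of leaf labels."""

    panel_id: str
    rules: tuple[PhenotypeRule, ...]
    groups: Mapping[str, frozenset] = field(default_factory=dict)
    fallback_label: str = FALLBACK_LABEL

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise SchemeError("duplicate rule labels in scheme")
        object.__setattr__(self, "rules", tuple(sorted(self.rules, key=lambda r: r.priority)))
        panel_markers = set(PANEL_MARKERS[self.panel_id])
        for rule in self.rules:
            extra = rule.marker_names - panel_markers
            if extra:
                raise SchemeError(
                    f"rule {rule.label!r} references markers {sorted(extra)} "
                    f"absent from panel {self.panel_id!r}"
                )
        leaf = set(labels) | {self.fallback_label}
        for gname, members in self.groups.items():
            unknown = set(members) - leaf
            if unknown:
                raise SchemeError(f"group {gname!r} references unknown leaves {sorted(unknown)}")

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.rules) + (self.fallback_label,)

    def resolve(self, label: Union[str, Iterable[str]]) -> frozenset:
        """Resolve a leaf or group label to its set of leaf labels."""
        if not isinstance(label, str):
            out: set[str] = set()
            for item in label:
                out |= self.resolve(item)
            return frozenset(out)
        if label in self.groups:
            return frozenset(self.groups[label])
        if label in self.leaf_labels:
            return frozenset({label})
        raise KeyError(f"unknown phenotype label {label!r} for panel {self.panel_id!r}")


def assign_phenotypes(site: TissueSite, scheme: PhenotypeScheme) -> TissueSite:
    """Label every cell of a site; returns a new site, count conserved.

    The scheme's panel must match the site's. A rule referencing a marker the
    site lacks fails *before* any assignment.
    """
    if scheme.panel_id != site.panel_id:
        raise SchemeError(
            f"scheme panel {scheme.panel_id!r} does not match site panel {site.panel_id!r}"
        )
    for rule in scheme.rules:
        missing = [m for m in rule.marker_names if m not in site.df.columns]
        if missing:
            raise SchemeError(
                f"rule {rule.label!r} references markers {missing} missing from site"
            )
    df = site.df.copy()
    n = len(df)
    env = {m: df[m].to_numpy(dtype=bool) for m in site.markers if m in df.columns}
    compartment = df["compartment"].to_numpy()
    labels = np.full(n, scheme.fallback_label, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in scheme.rules:
        mask = rule.mask(env) & unassigned
        if rule.compartment != "any":
            mask &= compartment == rule.compartment
        labels[mask] = rule.label
        unassigned &= ~mask
    df["phenotype"] = labels
    return replace(site, df=df)


# ---------------------------------------------------------------------------
# default schemes
# ---------------------------------------------------------------------------

def default_scheme(panel_id: str) -> PhenotypeScheme:
    """Gating scheme reconstructed from the marker biology of the panel.

    panel1 (CD8 axis): cancer (pan-CK+); dysfunctional CD8+ T cells
    (Tim3+, terminal state wins); predysfunctional CD8+ T cells
    (PD-1+ or CD103+, Tim3-); remaining CD8+ T cells. Group ``CD8_Ttotal``
    covers every CD8+ pan-CK- cell. GZMB is carried as an annotation flag
    only - no gate is defined on it.

    panel2 (stromal axis): hypoxic/normoxic cancer (pan-CK+/Hif-1a+-),
    regulatory and conventional CD4+ T cells (Foxp3+/-), cancer microvessels
    (CD31+), cancer-associated fibroblasts (aSMA+ CD31-). Groups ``cancer``
    and ``CD4_Ttotal``.

    ``combined`` merges both for single-site synthetic data.
    """
    if panel_id == "panel1":
        rules = (
            PhenotypeRule("cancer", "PANCK", 10),
            PhenotypeRule("CD8_Tdys", "CD8 & TIM3", 20),
            PhenotypeRule("CD8_Tpredys", "CD8 & (PD1 | CD103) & !TIM3", 30),
            PhenotypeRule("CD8_Ttotal", "CD8", 40),
        )
        groups = {"CD8_Ttotal": frozenset({"CD8_Ttotal", "CD8_Tpredys", "CD8_Tdys"})}
    elif panel_id == "panel2":
        rules = (
            PhenotypeRule("cancer_hypoxic", "PANCK & HIF1A", 10),
            PhenotypeRule("cancer_normoxic", "PANCK & !HIF1A", 11),
            PhenotypeRule("CD4_Treg", "CD4 & FOXP3", 20),
            PhenotypeRule("CD4_Tcon", "CD4 & !FOXP3", 21),
            PhenotypeRule("CMV", "CD31", 30),
            PhenotypeRule("CAF", "ASMA & !CD31", 40),
        )
        groups = {
            "cancer": frozenset({"cancer_hypoxic", "cancer_normoxic"}),
            "CD4_Ttotal": frozenset({"CD4_Treg", "CD4_Tcon"}),
        }
    elif panel_id == "combined":
        rules = (
            PhenotypeRule("cancer_hypoxic", "PANCK & HIF1A", 10),
            PhenotypeRule("cancer_normoxic", "PANCK & !HIF1A", 11),
            PhenotypeRule("CD8_Tdys", "CD8 & TIM3", 20),
            PhenotypeRule("CD8_Tpredys", "CD8 & (PD1 | CD103) & !TIM3", 21),
            PhenotypeRule("CD8_Ttotal", "CD8", 22),
            PhenotypeRule("CD4_Treg", "CD4 & FOXP3", 30),
            PhenotypeRule("CD4_Tcon", "CD4 & !FOXP3", 31),
            PhenotypeRule("CMV", "CD31", 40),
            PhenotypeRule("CAF", "ASMA & !CD31", 50),
        )
        groups = {
            "cancer": frozenset({"cancer_hypoxic", "cancer_normoxic"}),
            "CD8_Ttotal": frozenset({"CD8_Ttotal", "CD8_Tpredys", "CD8_Tdys"}),
            "CD4_Ttotal": frozenset({"CD4_Treg", "CD4_Tcon"}),
        }
    else:
        raise SchemeError(f"unknown panel {panel_id!r}")
    return PhenotypeScheme(panel_id=panel_id, rules=rules, groups=groups)


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

def save_scheme(scheme: PhenotypeScheme, path: Union[str, Path]) -> None:
    payload = {
        "panel": scheme.panel_id,
        "fallback": scheme.fallback_label,
        "rules": [
            {
                "label": r.label,
                "expression": r.expression,
                "priority": r.priority,
                **({"compartment": r.compartment} if r.compartment != "any" else {}),
            }
            for r in scheme.rules
        ],
        "groups": {g: sorted(m) for g, m in scheme.groups.items()},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_scheme(path: Union[str, Path]) -> PhenotypeScheme:
    raw = yaml.safe_load(Path(path).read_text())
    rules = tuple(
        PhenotypeRule(
            label=r["label"],
            expression=r["expression"],
            priority=int(r["priority"]),
            compartment=r.get("compartment", "any"),
        )
        for r in raw["rules"]
    )
    return PhenotypeScheme(
        panel_id=raw["panel"],
        rules=rules,
        groups={g: frozenset(m) for g, m in raw.get("groups", {}).items()},
        fallback_label=raw.get("fallback", FALLBACK_LABEL),
    )
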