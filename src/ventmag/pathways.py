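"""Rule-based metabolic pathway completeness calling.

Each pathway carries an ordered list of level rules — boolean expressions
over gene-symbol presence built from AND, OR and "at least k of" — that
are evaluated in precedence order (complete, then uncomplete, then
partial); the first match wins and the default is none.  Binary traits
(e.g. cyc2 iron oxidation, fermentation) use present/absent.  Because the
expressions contain no negation, adding a gene symbol can never lower a
pathway's level.

The built-in ruleset encodes the sulfur, nitrogen, carbon-fixation,
CO-oxidation, methane and oxidase pathways used for vent-chimney MAG
annotation; it ships as an editable YAML file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import yaml

log = logging.getLogger(__name__)

__all__ = [
    "PathwayRule", "PathwayRuleSet", "MagAnnotation", "builtin_ruleset",
    "classify", "classify_all", "count_cazymes", "mean_cazymes",
    "LEVELS", "LEVEL_CODES",
]

#: graded levels in precedence order (first match wins)
LEVELS = ("complete", "uncomplete", "partial")
#: matrix encoding used in serialized outputs
LEVEL_CODES = {"none": 0, "partial": 1, "uncomplete": 2, "complete": 3,
               "absent": 0, "present": 3}


def evaluate(expr, present: frozenset) -> bool:
    """Evaluate a rule expression against a set of present symbols.

    Expressions are symbols (strings) or nested dicts:
    ``{"all": [...]}", ``{"any": [...]}``, ``{"atleast": k, "of": [...]}``.
    """
    if isinstance(expr, str):
        return expr in present
    if not isinstance(expr, dict) or len(set(expr) - {"of"}) != 1:
        raise ValueError(f"malformed rule expression: {expr!r}")
    if "all" in expr:
        return all(evaluate(e, present) for e in expr["all"])
    if "any" in expr:
        return any(evaluate(e, present) for e in expr["any"])
    if "atleast" in expr:
        k = int(expr["atleast"])
        return sum(evaluate(e, present) for e in expr["of"]) >= k
    raise ValueError(f"unknown operator in {expr!r}")


def _symbols_of(expr) -> set[str]:
    if isinstance(expr, str):
        return {expr}
    items = expr.get("all") or expr.get("any") or expr.get("of") or []
    out: set[str] = set()
    for e in items:
        out |= _symbols_of(e)
    return out


@dataclass
class PathwayRule:
    name: str
    levels: list[tuple[str, object]]   # (level name, expression), precedence order
    binary: bool = False

    def __post_init__(self) -> None:
        order = ("present",) if self.binary else LEVELS
        names = [lv for lv, _ in self.levels]
        if [lv for lv in order if lv in names] != names:
            raise ValueError(f"{self.name}: levels must follow precedence "
                             f"order {order}, got {names}")

    @property
    def symbols(self) -> set[str]:
        out: set[str] = set()
        for _, expr in self.levels:
            out |= _symbols_of(expr)
        return out

    def classify(self, present: frozenset) -> str:
        for level, expr in self.levels:
            if evaluate(expr, present):
                return level
        return "absent" if self.binary else "none"


@dataclass
class PathwayRuleSet:
    pathways: dict[str, PathwayRule]
    notes: dict[str, str] = field(default_factory=dict)

    @property
    def vocabulary(self) -> set[str]:
        out: set[str] = set()
        for rule in self.pathways.values():
            out |= rule.symbols
        return out

    def to_dict(self) -> dict:
        return {
            "notes": dict(self.notes),
            "pathways": {
                name: {"binary": rule.binary,
                       "levels": [{"level": lv, "rule": expr}
                                  for lv, expr in rule.levels]}
                for name, rule in self.pathways.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PathwayRuleSet":
        pathways = {}
        for name, spec in data["pathways"].items():
            levels = [(lv["level"], lv["rule"]) for lv in spec["levels"]]
            pathways[name] = PathwayRule(name, levels,
                                         binary=bool(spec.get("binary")))
        return cls(pathways=pathways, notes=dict(data.get("notes", {})))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PathwayRuleSet":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class MagAnnotation:
    """Gene-presence annotation for one MAG."""

    bin_id: str
    symbols: frozenset
    cazyme_count: int = 0
    hydrogenase_groups: tuple = ()   # HydDB group labels, consumed as input

    def __post_init__(self) -> None:
        self.symbols = frozenset(self.symbols)
        if self.cazyme_count < 0:
            raise ValueError("CAZyme count must be >= 0")


def builtin_ruleset() -> PathwayRuleSet:
    """The shipped pathway-completeness grammar (editable YAML)."""
    text = (resources.files("ventmag") / "data" / "pathway_rules.yaml").read_text()
    return PathwayRuleSet.from_yaml(text)


def classify(present, pathway: str, rules: PathwayRuleSet) -> str:
    """Completeness level of one pathway for a gene-presence set."""
    if pathway not in rules.pathways:
        raise KeyError(f"unknown pathway {pathway!r}")
    return rules.pathways[pathway].classify(frozenset(present))


def classify_all(annotations: list[MagAnnotation],
                 rules: PathwayRuleSet):
    """Dense bin x pathway matrix of completeness levels.

    Symbols outside the rule vocabulary are logged and ignored (they
    cannot affect any rule).
    """
    import pandas as pd

    vocab = rules.vocabulary
    rows = {}
    for ann in annotations:
        unknown = set(ann.symbols) - vocab
        if unknown:
            log.info("bin %s: %d symbols outside rule vocabulary ignored",
                     ann.bin_id, len(unknown))
        present = frozenset(ann.symbols & vocab)
        rows[ann.bin_id] = {name: rule.classify(present)
                            for name, rule in rules.pathways.items()}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(rules.pathways))


def count_cazymes(annotation: MagAnnotation) -> int:
    """Number of CAZyme-labeled genes in one MAG (a heterotrophy proxy)."""
    return int(annotation.cazyme_count)


def mean_cazymes(annotations: list[MagAnnotation]) -> float:
    """Arithmetic mean CAZyme count over a group of MAGs."""
    if not annotations:
        raise ValueError("need at least one annotation")
    return float(sum(count_cazymes(a) for a in annotations) / len(annotations))
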