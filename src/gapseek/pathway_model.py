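"""Pathway definitions: a small line-oriented DSL, validation, expansion.

A pathway describes the biosynthesis of one compound as a set of *steps*
(single enzymatic reactions or subunits) combined by *rules*.  A rule lists
one or more alternative instantiations, each an ordered list of step ids
and/or other rule ids (subpathways).  The distinguished rule ``all``
defines the pathway; expanding its alternatives (recursively inlining
subpathways) yields every concrete candidate path.

DSL grammar (UTF-8 text, one pathway per file, ``#`` starts a comment)::

    pathway <pathway_id>
    <step_id>: <description> :: <matcher>[, <matcher> ...]
    ignore <step_id>: <matcher>[, <matcher> ...]
    <rule_id> = <item> [<item> ...] [| <item> [<item> ...]]...
    require <scope> present <pathway_id>.<step_id>
    require <scope> absent <pathway_id>.<step_id>

Matchers are ``EC:2.5.1.49`` (incomplete ECs like ``2.5.1.-`` allowed),
``term:<word>``, ``curated:<id>``, ``uniprot:<id>`` or ``hmm:<id>``; a bare
dotted EC number is also accepted.  A ``require`` line ties a pathway or
subpathway to a step of another pathway that must (or must not) be present
when the scope is on the selected best path.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class MatcherKind(enum.Enum):
    EC = "ec"
    TERM = "term"
    CURATED_ID = "curated"
    HMM = "hmm"
    UNIPROT = "uniprot"


_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-|n?\d*)$")


@dataclass(frozen=True)
class Matcher:
    kind: MatcherKind
    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("matcher value must be nonempty")
        if self.kind is MatcherKind.EC and not _EC_RE.match(self.value):
            raise ValueError(f"malformed EC number {self.value!r}")

    def to_text(self) -> str:
        return f"{self.kind.value.upper()}:{self.value}" if self.kind is MatcherKind.EC \
            else f"{self.kind.value}:{self.value}"


@dataclass
class StepDefinition:
    step_id: str
    description: str
    matchers: list[Matcher]
    ignore: list[Matcher] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.matchers:
            raise ValueError(f"step {self.step_id} has no matchers")


@dataclass
class Rule:
    rule_id: str
    # each instantiation is an ordered list of step ids / rule ids
    instantiations: list[list[str]]


class Polarity(enum.Enum):
    MUST_BE_PRESENT = "present"
    MUST_NOT_BE_PRESENT = "absent"


@dataclass(frozen=True)
class Requirement:
    scope: str  # pathway_id or rule_id within this pathway
    required_pathway: str
    required_step: str
    polarity: Polarity


@dataclass
class PathwayDefinition:
    pathway_id: str
    steps: dict[str, StepDefinition]
    rules: dict[str, Rule]
    requirements: list[Requirement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "all" not in self.rules:
            raise PathwayParseError(f"pathway {self.pathway_id} lacks an 'all' rule")


class PathwayParseError(ValueError):
    """Malformed pathway definition text."""


class ExpansionError(RuntimeError):
    """Path expansion exceeded the configured cap."""


def parse_matcher(token: str) -> Matcher:
    token = token.strip()
    if ":" in token:
        prefix, value = token.split(":", 1)
        prefix = prefix.strip().lower()
        value = value.strip()
        for kind in MatcherKind:
            if prefix == kind.value:
                return Matcher(kind, value)
        raise PathwayParseError(f"unknown matcher prefix {prefix!r} in {token!r}")
    if _EC_RE.match(token):
        return Matcher(MatcherKind.EC, token)
    raise PathwayParseError(f"cannot parse matcher {token!r}")


def _parse_matcher_list(text: str) -> list[Matcher]:
    return [parse_matcher(t) for t in text.split(",") if t.strip()]


def parse_pathway_file(text: str, pathway_id: str | None = None) -> PathwayDefinition:
    """Parse one pathway's DSL text into a fully linked definition.

    Raises :class:`PathwayParseError` naming the offending line for
    undefined references, duplicate step ids or cyclic rule references.
    """
    steps: dict[str, StepDefinition] = {}
    rules: dict[str, Rule] = {}
    requirements: list[Requirement] = []
    pending_ignores: list[tuple[int, str, list[Matcher]]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("pathway "):
            pid = line.split(None, 1)[1].strip()
            if pathway_id is not None and pid != pathway_id:
                raise PathwayParseError(
                    f"line {lineno}: pathway id {pid!r} does not match expected {pathway_id!r}"
                )
            pathway_id = pid
            continue
        if line.startswith("ignore "):
            body = line[len("ignore "):]
            if ":" not in body:
                raise PathwayParseError(f"line {lineno}: malformed ignore line")
            sid, matchers = body.split(":", 1)
            pending_ignores.append((lineno, sid.strip(), _parse_matcher_list(matchers)))
            continue
        if line.startswith("require "):
            parts = line.split()
            if len(parts) != 4 or parts[2] not in ("present", "absent"):
                raise PathwayParseError(
                    f"line {lineno}: expected 'require <scope> present|absent <pathway>.<step>'"
                )
            _, scope, polarity, target = parts
            if "." not in target:
                raise PathwayParseError(f"line {lineno}: requirement target must be pathway.step")
            tp, ts = target.split(".", 1)
            requirements.append(Requirement(scope, tp, ts, Polarity(polarity)))
            continue
        if "=" in line and (":" not in line or line.index("=") < line.index(":")):
            rid, rhs = line.split("=", 1)
            rid = rid.strip()
            if rid in rules:
                raise PathwayParseError(f"line {lineno}: duplicate rule {rid!r}")
            insts = []
            for alt in rhs.split("|"):
                items = alt.split()
                if not items:
                    raise PathwayParseError(f"line {lineno}: empty alternative in rule {rid!r}")
                insts.append(items)
            rules[rid] = Rule(rid, insts)
            continue
        if ":" in line:
            sid, rest = line.split(":", 1)
            sid = sid.strip()
            if sid in steps:
                raise PathwayParseError(f"line {lineno}: duplicate step {sid!r}")
            if "::" in rest:
                desc, matcher_text = rest.split("::", 1)
            else:
                raise PathwayParseError(
                    f"line {lineno}: step line must be '<id>: <description> :: <matchers>'"
                )
            matchers = _parse_matcher_list(matcher_text)
            if not matchers:
                raise PathwayParseError(f"line {lineno}: step {sid!r} has no matchers")
            steps[sid] = StepDefinition(sid, desc.strip(), matchers)
            continue
        raise PathwayParseError(f"line {lineno}: cannot parse {line!r}")

    if pathway_id is None:
        raise PathwayParseError("missing 'pathway <id>' line")
    for lineno, sid, matchers in pending_ignores:
        if sid not in steps:
            raise PathwayParseError(f"line {lineno}: ignore for undefined step {sid!r}")
        steps[sid].ignore.extend(matchers)

    if "all" not in rules:
        raise PathwayParseError(f"pathway {pathway_id!r} lacks an 'all' rule")
    defn = PathwayDefinition(pathway_id, steps, rules, requirements)
    _check_references(defn)
    _check_acyclic(defn)
    return defn


def _check_references(defn: PathwayDefinition) -> None:
    for rule in defn.rules.values():
        for inst in rule.instantiations:
            for item in inst:
                if item not in defn.steps and item not in defn.rules:
                    raise PathwayParseError(
                        f"undefined reference {item!r} in rule {rule.rule_id!r}"
                    )


def _check_acyclic(defn: PathwayDefinition) -> None:
    """DFS over the rule-reference graph; raises listing any cycle found."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {rid: WHITE for rid in defn.rules}
    stack: list[str] = []

    def visit(rid: str) -> None:
        color[rid] = GRAY
        stack.append(rid)
        for inst in defn.rules[rid].instantiations:
            for item in inst:
                if item in defn.rules:
                    if color[item] == GRAY:
                        cycle = stack[stack.index(item):] + [item]
                        raise PathwayParseError(
                            f"cyclic rule references: {' -> '.join(cycle)}"
                        )
                    if color[item] == WHITE:
                        visit(item)
        stack.pop()
        color[rid] = BLACK

    for rid in defn.rules:
        if color[rid] == WHITE:
            visit(rid)


def serialize_pathway(defn: PathwayDefinition) -> str:
    """Render a definition back to DSL text (parse/serialize round-trips)."""
    lines = [f"pathway {defn.pathway_id}"]
    for step in defn.steps.values():
        matchers = ", ".join(m.to_text() for m in step.matchers)
        lines.append(f"{step.step_id}: {step.description} :: {matchers}")
        if step.ignore:
            ign = ", ".join(m.to_text() for m in step.ignore)
            lines.append(f"ignore {step.step_id}: {ign}")
    for rule in defn.rules.values():
        alts = " | ".join(" ".join(inst) for inst in rule.instantiations)
        lines.append(f"{rule.rule_id} = {alts}")
    for req in defn.requirements:
        lines.append(
            f"require {req.scope} {req.polarity.value} "
            f"{req.required_pathway}.{req.required_step}"
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ExpandedPath:
    """One concrete alternative path: its steps and the rules it used."""

    step_ids: tuple[str, ...]
    rules_used: frozenset[str]


def expand_paths(defn: PathwayDefinition, cap: int = 10_000) -> list[list[str]]:
    """Every concrete alternative path of the pathway, in deterministic
    depth-first instantiation order.  Raises :class:`ExpansionError` if the
    number of paths would exceed ``cap`` (no silent truncation)."""
    return [list(p.step_ids) for p in expand_paths_detailed(defn, cap=cap)]


def expand_paths_detailed(defn: PathwayDefinition, cap: int = 10_000) -> list[ExpandedPath]:
    def expand_rule(rid: str) -> list[tuple[tuple[str, ...], frozenset[str]]]:
        rule = defn.rules[rid]
        out: list[tuple[tuple[str, ...], frozenset[str]]] = []
        for inst in rule.instantiations:
            # Cartesian product across items, left to right.
            partial: list[tuple[tuple[str, ...], frozenset[str]]] = [((), frozenset())]
            for item in inst:
                if item in defn.rules:
                    sub = expand_rule(item)
                else:
                    sub = [((item,), frozenset())]
                partial = [
                    (acc + seq, used | sub_used)
                    for acc, used in partial
                    for seq, sub_used in sub
                ]
                if len(partial) > cap:
                    raise ExpansionError(
                        f"expansion of pathway {defn.pathway_id!r} exceeds cap {cap}"
                    )
            out.extend((seq, used | {rid}) for seq, used in partial)
            if len(out) > cap:
                raise ExpansionError(
                    f"expansion of pathway {defn.pathway_id!r} exceeds cap {cap}"
                )
        return out

    expanded = expand_rule("all")
    if not expanded:
        raise ExpansionError(f"pathway {defn.pathway_id!r} expands to no paths")
    return [ExpandedPath(seq, used) for seq, used in expanded]


@dataclass
class ValidationFinding:
    pathway_id: str
    kind: str  # "unreachable step" | "unused rule" | "unresolvable requirement"
    detail: str


def validate_definitions(pathways: Sequence[PathwayDefinition]) -> list[ValidationFinding]:
    """Report-only validation across a pathway set.

    Flags steps never reachable from ``all``, rules never referenced, and
    requirements whose scope or target does not resolve.
    """
    findings: list[ValidationFinding] = []
    by_id = {p.pathway_id: p for p in pathways}
    for defn in pathways:
        reachable_steps: set[str] = set()
        used_rules: set[str] = {"all"}
        frontier = ["all"]
        while frontier:
            rid = frontier.pop()
            for inst in defn.rules[rid].instantiations:
                for item in inst:
                    if item in defn.rules:
                        if item not in used_rules:
                            used_rules.add(item)
                            frontier.append(item)
                    else:
                        reachable_steps.add(item)
        for sid in defn.steps:
            if sid not in reachable_steps:
                findings.append(ValidationFinding(defn.pathway_id, "unreachable step", sid))
        for rid in defn.rules:
            if rid not in used_rules:
                findings.append(ValidationFinding(defn.pathway_id, "unused rule", rid))
        for req in defn.requirements:
            if req.scope != defn.pathway_id and req.scope not in defn.rules:
                findings.append(
                    ValidationFinding(
                        defn.pathway_id, "unresolvable requirement",
                        f"scope {req.scope!r} is neither this pathway nor one of its rules",
                    )
                )
            target = by_id.get(req.required_pathway)
            if target is None or req.required_step not in target.steps:
                findings.append(
                    ValidationFinding(
                        defn.pathway_id, "unresolvable requirement",
                        f"target {req.required_pathway}.{req.required_step} does not exist",
                    )
                )
    return findings


def load_pathway_dir(path) -> list[PathwayDefinition]:
    """Load every ``*.steps`` file in a directory as one pathway each."""
    import pathlib

    p = pathlib.Path(path)
    defs = []
    for f in sorted(p.glob("*.steps")):
        defs.append(parse_pathway_file(f.read_text(), pathway_id=f.stem))
    if not defs:
        raise PathwayParseError(f"no *.steps pathway files in {path}")
    return defs
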