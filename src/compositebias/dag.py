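"""Causal DAGs with deterministic (fully determined) nodes.

The graphs handled here contain four kinds of node:

``probabilistic``
    an observed variable with its own exogenous noise (e.g. baseline weight);
``latent``
    an unobserved variable (true height, self-report error) that participates
    in paths like any other node but can never be conditioned on;
``proxy``
    an observed variable fully determined by at least one latent (self-reported
    height = true height + report error; measured height = true height);
``composite``
    an observed variable fully determined by other *observed* variables
    (BMI, change scores, relative changes).

Deterministic nodes obey two structural rules: nothing points into them except
their declared determinants, and they never feed the probabilistic layer — a
composite's causal content is carried entirely by its determinants, so a
"forward arc" out of one would double-count it.  A deterministic node may feed
another deterministic node that declares it (BMI change is determined by the
two BMI values).

Conditioning is restricted accordingly: proxies are conditionable (they are
what an analyst actually measures), composites of observed variables are not,
because graphical identification theory has nothing to say about conditioning
on a degenerate (zero-noise) function of observed variables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import names as N

PROBABILISTIC = "probabilistic"
LATENT = "latent"
PROXY = "proxy"
COMPOSITE = "composite"

NODE_KINDS = (PROBABILISTIC, LATENT, PROXY, COMPOSITE)

#: combination rules a deterministic node may declare
FORMULA_RULES = ("sum", "difference", "relative-difference", "bmi")


@dataclass(frozen=True)
class Formula:
    """Combination rule of a deterministic node.

    ``determinants`` is ordered: for ``difference`` and
    ``relative-difference`` it is (follow, base); for ``bmi`` it is
    (weight [kg], height [cm]); ``sum`` accepts any arity >= 1.
    """

    rule: str
    determinants: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rule not in FORMULA_RULES:
            raise ValueError(f"unknown formula rule {self.rule!r}")
        if self.rule != "sum" and len(self.determinants) != 2:
            raise ValueError(f"rule {self.rule!r} takes exactly 2 determinants")
        if not self.determinants:
            raise ValueError("formula needs at least one determinant")


@dataclass
class CausalDag:
    """Directed acyclic graph over probabilistic, latent, proxy and composite nodes."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- construction -----------------------------------------------------

    def add_node(
        self,
        name: str,
        kind: str = PROBABILISTIC,
        rank: int = 0,
        formula: Formula | None = None,
    ) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        if kind in (PROXY, COMPOSITE) and formula is None:
            raise ValueError(f"{kind} node {name!r} requires a formula")
        if kind in (PROBABILISTIC, LATENT) and formula is not None:
            raise ValueError(f"{kind} node {name!r} must not carry a formula")
        self.graph.add_node(name, kind=kind, rank=rank, formula=formula)
        if formula is not None:
            for d in formula.determinants:
                self.graph.add_edge(d, name)

    def add_edge(self, cause: str, effect: str) -> None:
        for n in (cause, effect):
            if n not in self.graph:
                raise KeyError(f"node {n!r} not in DAG")
        self.graph.add_edge(cause, effect)

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    def rank(self, node: str) -> int:
        return self.graph.nodes[node]["rank"]

    def formula(self, node: str) -> Formula | None:
        return self.graph.nodes[node].get("formula")

    def parents(self, node: str) -> set[str]:
        return set(self.graph.predecessors(node))

    def children(self, node: str) -> set[str]:
        return set(self.graph.successors(node))

    def ancestors(self, node: str) -> set[str]:
        return nx.ancestors(self.graph, node)

    def descendants(self, node: str) -> set[str]:
        return nx.descendants(self.graph, node)

    def nodes_of_kind(self, *kinds: str) -> list[str]:
        return [n for n in self.graph.nodes if self.kind(n) in kinds]

    def is_deterministic(self, node: str) -> bool:
        return self.kind(node) in (PROXY, COMPOSITE)

    def topological_order(self) -> list[str]:
        """Nodes sorted by temporal rank, ties broken topologically."""
        order = list(nx.lexicographical_topological_sort(
            self.graph, key=lambda n: (self.rank(n), n)))
        return order

    def proxies_of(self, latent: str) -> list[str]:
        """Observed proxy nodes that declare ``latent`` as a determinant."""
        out = []
        for n in self.nodes_of_kind(PROXY):
            f = self.formula(n)
            if f is not None and latent in f.determinants:
                out.append(n)
        return sorted(out, key=self.rank)

    # -- validation -------------------------------------------------------

    def validate(self) -> list[str]:
        """Check the deterministic-node rules; return human-readable violations.

        An empty list means the graph is admissible.  Violations are
        returned, not raised, so a user-supplied graph can be reported on
        in full.
        """
        if len(self.graph) == 0:
            raise ValueError("DAG must contain at least one node")
        violations: list[str] = []
        if not nx.is_directed_acyclic_graph(self.graph):
            cyc = nx.find_cycle(self.graph)
            violations.append(f"graph contains a cycle: {cyc}")
            return violations

        for node in self.graph.nodes:
            kind = self.kind(node)
            if kind in (PROXY, COMPOSITE):
                f = self.formula(node)
                if f is None:
                    violations.append(f"{kind} node {node!r} has no formula")
                    continue
                declared = set(f.determinants)
                actual = self.parents(node)
                for extra in sorted(actual - declared):
                    violations.append(
                        f"edge {extra!r} -> {node!r}: non-determinant arc into "
                        f"fully determined node {node!r}")
                for missing in sorted(declared - actual):
                    violations.append(
                        f"{kind} node {node!r} misses determinant edge from {missing!r}")
                for child in sorted(self.children(node)):
                    child_formula = self.formula(child)
                    determined_by_node = (
                        child_formula is not None and node in child_formula.determinants)
                    if not (self.is_deterministic(child) and determined_by_node):
                        violations.append(
                            f"edge {node!r} -> {child!r}: forward arc from fully "
                            f"determined node {node!r}")
                if kind == PROXY:
                    if not any(self.kind(d) == LATENT for d in f.determinants
                               if d in self.graph):
                        violations.append(
                            f"proxy node {node!r} has no latent determinant")
                if kind == COMPOSITE:
                    if any(d in self.graph and self.kind(d) == LATENT
                           for d in f.determinants):
                        violations.append(
                            f"composite node {node!r} is determined by a latent; "
                            f"composites combine observed variables only")
        return violations

    # -- d-separation -----------------------------------------------------

    def _skeleton(self) -> nx.DiGraph:
        """Subgraph over probabilistic/latent/proxy nodes (composites dropped)."""
        keep = [n for n in self.graph.nodes if self.kind(n) != COMPOSITE]
        return self.graph.subgraph(keep)

    def d_separated(self, a: str, b: str, given: set[str] | frozenset[str] = frozenset()) -> bool:
        """Standard d-separation over the probabilistic/latent/proxy skeleton.

        Composites are derived quantities, not conditionable, and never appear
        on identification-relevant paths; conditioning on one is rejected.
        Latents likewise cannot be conditioned on (they are unobserved).
        """
        given = set(given)
        if a == b:
            raise ValueError("query nodes must be distinct")
        if a in given or b in given:
            raise ValueError("query nodes may not be in the conditioning set")
        for z in given:
            if self.kind(z) == COMPOSITE:
                raise ValueError(
                    f"cannot condition on composite node {z!r}: fully determined "
                    f"variables are derived quantities, and graphical "
                    f"identification only licenses conditioning on "
                    f"probabilistic variables")
            if self.kind(z) == LATENT:
                raise ValueError(f"cannot condition on latent node {z!r}")
        for q in (a, b):
            if self.kind(q) == COMPOSITE:
                raise ValueError(
                    f"composite node {q!r} cannot be a d-separation endpoint; "
                    f"query its determinants instead")
        return self._d_separated_unchecked(a, b, given)

    def _d_separated_unchecked(self, a: str, b: str, given: set[str]) -> bool:
        return nx.is_d_separator(self._skeleton(), {a}, {b}, given)

    # -- covariate roles --------------------------------------------------

    def _effective(self, node: str) -> set[str]:
        """A proxy stands in for its latent determinants in role logic."""
        if self.kind(node) == PROXY:
            f = self.formula(node)
            return {d for d in f.determinants if self.kind(d) == LATENT}
        return {node}

    def _effective_descendants(self, node: str) -> set[str]:
        out: set[str] = set()
        for e in self._effective(node):
            out |= self.descendants(e)
        return out - {node}

    def classify_role(self, exposure: str, outcome: str, candidate: str) -> str:
        """Classify ``candidate`` as ``confounder``, ``mediator`` or ``neither``.

        A mediator lies on a causal path exposure -> ... -> outcome; a
        confounder is a common cause of both.  Proxy candidates inherit the
        role of the latent(s) they measure — self-reported height confounds
        wherever true height does.
        """
        if candidate in (exposure, outcome):
            raise ValueError("candidate must differ from exposure and outcome")
        for node, role in ((exposure, "exposure"), (outcome, "outcome"),
                           (candidate, "candidate")):
            if self.kind(node) == COMPOSITE:
                raise ValueError(f"{role} {node!r} is a composite node")
        exp_desc = self._effective_descendants(exposure)
        out_anc = self.ancestors(outcome)
        exp_anc = self.ancestors(exposure)
        for c in self._effective(candidate):
            if c in exp_desc and c in out_anc:
                return "mediator"
        for c in self._effective(candidate):
            if c in exp_anc and c in out_anc and c not in exp_desc:
                return "confounder"
        return "neither"

    # -- adjustment sets --------------------------------------------------

    def adjustment_set(
        self,
        exposure: str,
        outcome: str,
        prefer_proxy: dict[str, str] | None = None,
        exclude: frozenset[str] | set[str] = frozenset(),
        verify: bool = True,
    ) -> set[str]:
        """All-observed-pretreatment-ancestors adjustment set.

        Returns every observed non-descendant of the exposure that is an
        ancestor of the exposure or the outcome, substituting a proxy for a
        latent ancestor (the temporally earliest eligible proxy by default;
        override per latent via ``prefer_proxy``).  ``exclude`` removes named
        covariates, supporting the no-mutual-birth-adjustment convention.

        When ``verify`` is true the set is checked against the backdoor
        criterion by d-separation on the graph with the exposure's outgoing
        edges removed, treating each proxy as its latent determinants (the
        proxy is the analyst's stand-in for the latent).
        """
        if self.kind(exposure) == COMPOSITE:
            raise ValueError(
                f"composite node {exposure!r} cannot be an exposure: its causal "
                f"content belongs to its determinants")
        if self.rank(exposure) >= self.rank(outcome):
            raise ValueError(
                f"exposure {exposure!r} must temporally precede outcome {outcome!r}")
        exclude = set(exclude)
        exp_desc = self._effective_descendants(exposure)
        pool = (self.ancestors(exposure) | self.ancestors(outcome))
        pool -= {exposure, outcome}
        pool -= exp_desc

        out: set[str] = set()
        for node in pool:
            kind = self.kind(node)
            if kind == PROBABILISTIC:
                out.add(node)
            elif kind == LATENT:
                chosen = None
                if prefer_proxy and node in prefer_proxy:
                    chosen = prefer_proxy[node]
                    if chosen not in self.proxies_of(node):
                        raise ValueError(
                            f"{chosen!r} is not a proxy of latent {node!r}")
                else:
                    for p in self.proxies_of(node):  # rank-sorted
                        if p not in exp_desc and p not in (exposure, outcome):
                            chosen = p
                            break
                if chosen is not None and chosen not in exp_desc and \
                        chosen not in (exposure, outcome):
                    out.add(chosen)
        out -= exclude
        # deliberate exclusions (sensitivity variants, alternative conventions)
        # knowingly abandon backdoor closure; only the canonical set is verified
        if exclude:
            verify = False
        if verify and not self._satisfies_backdoor(exposure, outcome, out):
            raise RuntimeError(
                f"internal error: adjustment set {sorted(out)} fails the "
                f"backdoor criterion for {exposure!r} -> {outcome!r}")
        return out

    def _satisfies_backdoor(self, exposure: str, outcome: str, zset: set[str]) -> bool:
        """Backdoor check with proxies replaced by their latent determinants.

        A proxy exposure stands for its latent determinant(s): the check is
        run on each effective exposure node with that node's outgoing edges
        removed.
        """
        z_eff: set[str] = set()
        for z in zset:
            z_eff |= self._effective(z)
        exp_eff = self._effective(exposure)
        z_eff -= exp_eff | {exposure, outcome}
        for e in exp_eff:
            trimmed = CausalDag(nx.DiGraph(self.graph))
            trimmed.graph.remove_edges_from(list(self.graph.out_edges(e)))
            if not trimmed._d_separated_unchecked(e, outcome, z_eff):
                return False
        return True

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        nodes = []
        for n in self.topological_order():
            rec: dict = {"name": n, "kind": self.kind(n), "rank": self.rank(n)}
            f = self.formula(n)
            if f is not None:
                rec["formula"] = {"rule": f.rule, "determinants": list(f.determinants)}
            nodes.append(rec)
        edges = sorted(
            (c, e) for c, e in self.graph.edges
            if not (self.formula(e) and c in self.formula(e).determinants))
        # determinant edges are implied by formulas; only free edges are listed
        return {"nodes": nodes, "edges": [list(e) for e in edges]}

    @classmethod
    def from_dict(cls, data: dict) -> "CausalDag":
        dag = cls()
        for rec in data["nodes"]:
            f = rec.get("formula")
            formula = Formula(f["rule"], tuple(f["determinants"])) if f else None
            dag.add_node(rec["name"], kind=rec["kind"], rank=rec["rank"],
                         formula=formula)
        for cause, effect in data.get("edges", []):
            dag.add_edge(cause, effect)
        return dag

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CausalDag":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


def validate(dag: CausalDag) -> list[str]:
    """Module-level alias for :meth:`CausalDag.validate`."""
    return dag.validate()


def d_separated(dag: CausalDag, a: str, b: str, given=frozenset()) -> bool:
    return dag.d_separated(a, b, given)


def classify_role(dag: CausalDag, exposure: str, outcome: str, candidate: str) -> str:
    return dag.classify_role(exposure, outcome, candidate)


def adjustment_set(dag: CausalDag, exposure: str, outcome: str, **kw) -> set[str]:
    return dag.adjustment_set(exposure, outcome, **kw)


def ncds_dag() -> CausalDag:
    """The study DAG for the 1958 British birth cohort weight analysis.

    Temporal order: ethnicity and sex (birth) -> latent true height ->
    latent self-report error -> self-reported height (proxy) -> baseline
    weight (age 23) -> economic status -> malaise -> follow-up weight
    (age 33) -> measured height (error-free proxy of true height).  Every
    probabilistic variable is a possible cause of every later probabilistic
    variable; the six composite outcomes are fully determined per their
    formulas and feed nothing.
    """
    dag = CausalDag()
    dag.add_node(N.ETHNICITY, PROBABILISTIC, rank=0)
    dag.add_node(N.SEX, PROBABILISTIC, rank=0)
    dag.add_node(N.TRUE_HEIGHT, LATENT, rank=1)
    dag.add_node(N.SELF_REPORT_ERROR, LATENT, rank=2)
    dag.add_node(N.HEIGHT_SELF, PROXY, rank=3,
                 formula=Formula("sum", (N.TRUE_HEIGHT, N.SELF_REPORT_ERROR)))
    dag.add_node(N.WEIGHT_BASE, PROBABILISTIC, rank=4)
    dag.add_node(N.ECONOMIC_STATUS, PROBABILISTIC, rank=5)
    dag.add_node(N.MALAISE, PROBABILISTIC, rank=6)
    dag.add_node(N.WEIGHT_FOLLOW, PROBABILISTIC, rank=7)
    dag.add_node(N.HEIGHT_MEASURED, PROXY, rank=8,
                 formula=Formula("sum", (N.TRUE_HEIGHT,)))

    # birth variables cause everything downstream (possible-cause convention)
    later = [N.TRUE_HEIGHT, N.WEIGHT_BASE, N.ECONOMIC_STATUS, N.MALAISE,
             N.WEIGHT_FOLLOW]
    for birth in (N.ETHNICITY, N.SEX):
        for child in later:
            dag.add_edge(birth, child)
    for child in (N.WEIGHT_BASE, N.ECONOMIC_STATUS, N.MALAISE, N.WEIGHT_FOLLOW):
        dag.add_edge(N.TRUE_HEIGHT, child)
    for child in (N.ECONOMIC_STATUS, N.MALAISE, N.WEIGHT_FOLLOW):
        dag.add_edge(N.WEIGHT_BASE, child)
    for child in (N.MALAISE, N.WEIGHT_FOLLOW):
        dag.add_edge(N.ECONOMIC_STATUS, child)
    dag.add_edge(N.MALAISE, N.WEIGHT_FOLLOW)

    dag.add_node(N.BMI_BASE, COMPOSITE, rank=9,
                 formula=Formula("bmi", (N.WEIGHT_BASE, N.HEIGHT_SELF)))
    dag.add_node(N.BMI_FOLLOW, COMPOSITE, rank=9,
                 formula=Formula("bmi", (N.WEIGHT_FOLLOW, N.HEIGHT_MEASURED)))
    dag.add_node(N.WEIGHT_CHANGE, COMPOSITE, rank=9,
                 formula=Formula("difference", (N.WEIGHT_FOLLOW, N.WEIGHT_BASE)))
    dag.add_node(N.REL_WEIGHT_CHANGE, COMPOSITE, rank=9,
                 formula=Formula("relative-difference",
                                 (N.WEIGHT_FOLLOW, N.WEIGHT_BASE)))
    dag.add_node(N.BMI_CHANGE, COMPOSITE, rank=10,
                 formula=Formula("difference", (N.BMI_FOLLOW, N.BMI_BASE)))
    dag.add_node(N.REL_BMI_CHANGE, COMPOSITE, rank=10,
                 formula=Formula("relative-difference",
                                 (N.BMI_FOLLOW, N.BMI_BASE)))
    return dag
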