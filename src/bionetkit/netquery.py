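"""Path and pattern queries over heterogeneous molecular networks.

Networks mix typed edges — protein-protein interactions, TF-DNA binding,
co-expression, co-citation, pathway steps — some directed, some not. The
query engine enumerates simple regulatory paths between node sets, finds
common regulators and common targets, connects gene sets to curated pathways
(hypergeometric overlap), filters nodes/edges by logical attribute
conditions, and overlays expression or co-expression evidence as attributes.
SIF plus a tab-delimited attribute sidecar is the on-disk form.
"""

from __future__ import annotations

import fnmatch
import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from bionetkit.enrichment import hypergeom_tail

RELATION_TYPES = ("ppi", "tf_dna", "coexpression", "cocitation", "pathway_step", "other")

#: enumeration guard for path queries on dense graphs
MAX_PATHS = 100_000


@dataclass
class InteractionRecord:
    """A typed, optionally directed edge with evidence annotations."""

    source_id: str
    target_id: str
    relation_type: str = "other"
    directed: bool = False
    effect: str = "unknown"  # positive | negative | unknown
    mechanism: str | None = None
    p_value: float | None = None
    attributes: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        if self.relation_type not in RELATION_TYPES:
            raise ValueError(f"unknown relation_type {self.relation_type!r}")
        if self.effect not in ("positive", "negative", "unknown"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.p_value is not None and not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")

    def key(self):
        return (self.source_id, self.target_id, self.relation_type, self.provenance)


class Network:
    """Nodes with attribute maps plus a deduplicated typed edge list."""

    def __init__(self, edges: list[InteractionRecord] | None = None,
                 nodes: dict[str, dict] | None = None):
        self.node_attrs: dict[str, dict] = {n: dict(a) for n, a in (nodes or {}).items()}
        self.edges: list[InteractionRecord] = []
        self._edge_keys: set = set()
        for e in edges or []:
            self.add_edge(e)

    @property
    def nodes(self) -> set[str]:
        return set(self.node_attrs)

    def add_node(self, node_id: str, **attrs) -> None:
        self.node_attrs.setdefault(node_id, {}).update(attrs)

    def add_edge(self, edge: InteractionRecord) -> None:
        if edge.key() in self._edge_keys:
            return
        self._edge_keys.add(edge.key())
        self.edges.append(edge)
        self.add_node(edge.source_id)
        self.add_node(edge.target_id)

    def copy(self) -> "Network":
        net = Network()
        for n, a in self.node_attrs.items():
            net.add_node(n, **a)
        for e in self.edges:
            net.add_edge(InteractionRecord(
                e.source_id, e.target_id, e.relation_type, e.directed, e.effect,
                e.mechanism, e.p_value, dict(e.attributes), e.provenance,
            ))
        return net

    def to_digraph(self, direction: str = "directed",
                   edge_filter=None) -> nx.DiGraph:
        """Traversal graph: 'directed' honours each edge's flag (undirected
        edges go both ways); 'undirected'/'either' make every edge two-way."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.node_attrs))
        for e in sorted(self.edges, key=lambda e: e.key()):
            if edge_filter is not None and not edge_filter(e):
                continue
            g.add_edge(e.source_id, e.target_id)
            if direction in ("undirected", "either") or not e.directed:
                g.add_edge(e.target_id, e.source_id)
        return g


# ---------------------------------------------------------------------------
# queries


@dataclass
class PathResult:
    paths: list[tuple[str, ...]]
    truncated: bool = False

    def __iter__(self):
        return iter(self.paths)

    def __len__(self):
        return len(self.paths)


def find_paths(
    net: Network,
    sources,
    targets,
    max_len: int = 3,
    direction: str = "directed",
    edge_filter=None,
    max_paths: int = MAX_PATHS,
) -> PathResult:
    """All simple paths of length <= max_len from any source to any target.

    ``direction`` is one of directed/undirected/either (see
    :meth:`Network.to_digraph`); ``edge_filter`` is a predicate on
    InteractionRecord (e.g. a p-value cutoff). Paths are deduplicated and
    sorted by (length, node ids); enumeration stops at ``max_paths`` with the
    truncation flag set.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if direction not in ("directed", "undirected", "either"):
        raise ValueError(f"unknown direction {direction!r}")
    sources = sorted(set(sources))
    targets = sorted(set(targets))
    present = [s for s in sources if s in net.node_attrs]
    if not present:
        warnings.warn("no query source is present in the network")
        return PathResult([])
    g = net.to_digraph(direction, edge_filter)
    found: set[tuple[str, ...]] = set()
    truncated = False
    target_set = set(t for t in targets if t in net.node_attrs)
    for s in present:
        for path in nx.all_simple_paths(g, s, target_set, cutoff=max_len):
            found.add(tuple(path))
            if len(found) >= max_paths:
                truncated = True
                break
        if truncated:
            break
    paths = sorted(found, key=lambda p: (len(p), p))
    return PathResult(paths, truncated)


def _regulatory_digraph(net: Network) -> nx.DiGraph:
    """Directed regulation edges only (tf_dna or any directed edge)."""
    g = nx.DiGraph()
    g.add_nodes_from(net.node_attrs)
    for e in net.edges:
        if e.relation_type == "tf_dna" or e.directed:
            g.add_edge(e.source_id, e.target_id)
    return g


def common_regulators(net: Network, node_set) -> set[str]:
    """Nodes with a directed regulation edge into every member of node_set."""
    members = set(node_set)
    if not members:
        raise ValueError("node_set must be non-empty")
    g = _regulatory_digraph(net)
    regs: set[str] | None = None
    for m in sorted(members):
        preds = set(g.predecessors(m)) if m in g else set()
        regs = preds if regs is None else regs & preds
    return (regs or set()) - members


def common_targets(net: Network, node_set) -> set[str]:
    """Nodes receiving a directed regulation edge from every member."""
    members = set(node_set)
    if not members:
        raise ValueError("node_set must be non-empty")
    g = _regulatory_digraph(net)
    targs: set[str] | None = None
    for m in sorted(members):
        succ = set(g.successors(m)) if m in g else set()
        targs = succ if targs is None else targs & succ
    return (targs or set()) - members


def connect_to_pathways(
    gene_set,
    pathway_collection: dict[str, set],
    background: set | None = None,
) -> list[dict]:
    """Curated pathways overlapping a gene set, with hypergeometric p.

    Returns one dict per pathway with >= 1 overlapping gene: name, k (overlap),
    M (pathway size), n, N and the enrichment p against the background
    (default: union of all pathway genes plus the query). Sorted by p then name.
    """
    if not pathway_collection:
        raise ValueError("pathway_collection must be non-empty")
    genes = set(gene_set)
    if background is None:
        background = set().union(*pathway_collection.values()) | genes
    background = set(background)
    n = len(genes & background)
    out = []
    for name in sorted(pathway_collection):
        members = set(pathway_collection[name]) & background
        k = len(genes & members)
        if k == 0:
            continue
        p = hypergeom_tail(k, n, len(members), len(background))
        out.append({"pathway": name, "k": k, "M": len(members),
                    "n": n, "N": len(background), "p": p})
    out.sort(key=lambda d: (d["p"], d["pathway"]))
    return out


# ---------------------------------------------------------------------------
# attribute search


_OPERATORS = ("=", "!=", "<", "<=", ">", ">=", "contains", "matches")


def _edge_fields(e: InteractionRecord) -> dict:
    d = {
        "source_id": e.source_id, "target_id": e.target_id,
        "relation_type": e.relation_type, "directed": e.directed,
        "effect": e.effect, "mechanism": e.mechanism,
        "p_value": e.p_value, "provenance": e.provenance,
    }
    d.update(e.attributes)
    return d


def _eval_leaf(fields: dict, cond: dict, known_fields: set[str]):
    op = cond["op"]
    name = cond["field"]
    if name not in known_fields:
        raise KeyError(f"unknown field: {name!r}")
    if op not in _OPERATORS:
        raise ValueError(f"unknown operator {op!r}")
    actual = fields.get(name)
    value = cond["value"]
    if op in ("<", "<=", ">", ">="):
        if actual is None:
            return False
        try:
            a, v = float(actual), float(value)
        except (TypeError, ValueError):
            raise TypeError(
                f"numeric comparison on non-numeric field {name!r}"
            ) from None
        return {"<": a < v, "<=": a <= v, ">": a > v, ">=": a >= v}[op]
    if op == "=":
        return actual == value or str(actual) == str(value)
    if op == "!=":
        return not (actual == value or str(actual) == str(value))
    if actual is None:
        return False
    if op == "contains":
        return str(value).lower() in str(actual).lower()
    return fnmatch.fnmatchcase(str(actual).lower(), str(value).lower())


def _eval_condition(fields: dict, cond: dict, known_fields: set[str]) -> bool:
    """Evaluate an AND/OR/NOT condition tree over one attribute map."""
    if "and" in cond:
        return all(_eval_condition(fields, c, known_fields) for c in cond["and"])
    if "or" in cond:
        return any(_eval_condition(fields, c, known_fields) for c in cond["or"])
    if "not" in cond:
        return not _eval_condition(fields, cond["not"], known_fields)
    return _eval_leaf(fields, cond, known_fields)


def parse_condition(text: str) -> dict:
    """Parse a small infix condition string into a condition tree.

    Grammar: leaf = ``field op value``; combinators AND/OR/NOT and
    parentheses, case-insensitive. A JSON object is accepted verbatim.
    Example: ``(relation_type = tf_dna) AND (p_value < 1e-3)``.
    """
    text = text.strip()
    if text.startswith("{"):
        return json.loads(text)
    tokens: list[str] = []
    buf = ""
    for ch in text:
        if ch in "()":
            if buf.strip():
                tokens.extend(buf.split())
            buf = ""
            tokens.append(ch)
        else:
            buf += ch
    if buf.strip():
        tokens.extend(buf.split())

    def parse_or(pos: int) -> tuple[dict, int]:
        left, pos = parse_and(pos)
        items = [left]
        while pos < len(tokens) and tokens[pos].upper() == "OR":
            nxt, pos = parse_and(pos + 1)
            items.append(nxt)
        return (items[0] if len(items) == 1 else {"or": items}), pos

    def parse_and(pos: int) -> tuple[dict, int]:
        left, pos = parse_not(pos)
        items = [left]
        while pos < len(tokens) and tokens[pos].upper() == "AND":
            nxt, pos = parse_not(pos + 1)
            items.append(nxt)
        return (items[0] if len(items) == 1 else {"and": items}), pos

    def parse_not(pos: int) -> tuple[dict, int]:
        if pos < len(tokens) and tokens[pos].upper() == "NOT":
            inner, pos = parse_not(pos + 1)
            return {"not": inner}, pos
        return parse_atom(pos)

    def parse_atom(pos: int) -> tuple[dict, int]:
        if pos >= len(tokens):
            raise ValueError("condition ended unexpectedly")
        if tokens[pos] == "(":
            inner, pos = parse_or(pos + 1)
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError("unbalanced parenthesis in condition")
            return inner, pos + 1
        if len(tokens) - pos < 3:
            raise ValueError(f"incomplete condition near {' '.join(tokens[pos:])!r}")
        field_name, op = tokens[pos], tokens[pos + 1]
        value_tokens = []
        pos += 2
        while pos < len(tokens) and tokens[pos] not in (")",) \
                and tokens[pos].upper() not in ("AND", "OR"):
            value_tokens.append(tokens[pos])
            pos += 1
        if not value_tokens:
            raise ValueError(f"missing value for field {field_name!r}")
        return {"field": field_name, "op": op, "value": " ".join(value_tokens)}, pos

    tree, pos = parse_or(0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in condition: {tokens[pos:]!r}")
    return tree


def attribute_search(
    net: Network,
    condition: dict | str,
    over: str = "edges",
) -> list:
    """Exact-filter nodes or edges by a logical attribute condition.

    ``condition`` is a JSON-style tree ({"and": [...]}, {"or": [...]},
    {"not": ...}, or a leaf {"field", "op", "value"}) or an infix string for
    :func:`parse_condition`. Unknown fields and type mismatches raise.
    """
    if isinstance(condition, str):
        condition = parse_condition(condition)
    if over == "edges":
        known = {
            "source_id", "target_id", "relation_type", "directed", "effect",
            "mechanism", "p_value", "provenance",
        }
        for e in net.edges:
            known.update(e.attributes)
        return [e for e in net.edges
                if _eval_condition(_edge_fields(e), condition, known)]
    if over == "nodes":
        known = {"id"}
        for attrs in net.node_attrs.values():
            known.update(attrs)
        return sorted(
            n for n, attrs in net.node_attrs.items()
            if _eval_condition({"id": n, **attrs}, condition, known)
        )
    raise ValueError("over must be 'edges' or 'nodes'")


# ---------------------------------------------------------------------------
# overlays


def overlay(
    net: Network,
    coexpression_results=None,
    node_values: dict[str, float] | None = None,
    theme_clusters: dict | None = None,
    registry=None,
) -> Network:
    """Annotate a network with expression/co-expression/theme evidence.

    Co-expression results become ``coexpression_support`` / ``coexpression_r``
    attributes on matching edges (new coexpression edges are added for pairs
    absent from the network but with both endpoints present); per-node values
    become a ``z`` node attribute; theme clusters add a ``themes`` list
    attribute. Topology of existing edges never changes; node count is
    unchanged. Ids may be resolved through an entity registry when given;
    unresolvable ids are reported via warning.
    """
    out = net.copy()

    def resolve(name: str) -> str | None:
        if name in out.node_attrs:
            return name
        if registry is not None:
            for ent in registry.find_by_name(name):
                if ent.canonical_id in out.node_attrs:
                    return ent.canonical_id
        return None

    unresolved: set[str] = set()
    for res in coexpression_results or []:
        members = [resolve(m) for m in res.members]
        unresolved.update(m for m, r in zip(res.members, members) if r is None)
        if any(m is None for m in members) or len(members) != 2:
            continue
        a, b = members
        matched = False
        for e in out.edges:
            if {e.source_id, e.target_id} == {a, b}:
                e.attributes["coexpression_support"] = res.support
                e.attributes["coexpression_r"] = round(res.mean_abs_r, 6)
                matched = True
        if not matched:
            out.add_edge(InteractionRecord(
                a, b, "coexpression", directed=False,
                attributes={"coexpression_support": res.support,
                            "coexpression_r": round(res.mean_abs_r, 6)},
                provenance="overlay",
            ))
    for name, value in (node_values or {}).items():
        node = resolve(name)
        if node is None:
            unresolved.add(name)
            continue
        out.node_attrs[node]["z"] = value
    for theme, genes in (theme_clusters or {}).items():
        for name in genes:
            node = resolve(name)
            if node is None:
                unresolved.add(name)
                continue
            themes = out.node_attrs[node].setdefault("themes", [])
            if str(theme) not in themes:
                themes.append(str(theme))
    if unresolved:
        warnings.warn(f"{len(unresolved)} overlay id(s) could not be resolved")
    return out


# ---------------------------------------------------------------------------
# SIF + attribute sidecar I/O


def write_sif(net: Network, path, attributes_path=None) -> None:
    """Write ``source\\trelation\\ttarget`` lines (sorted, deduplicated).

    When ``attributes_path`` is given, a tab-delimited edge-attribute sidecar
    is written with the standard evidence columns plus any extra attributes
    serialized as JSON.
    """
    edges = sorted(net.edges, key=lambda e: e.key())
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.source_id}\t{e.relation_type}\t{e.target_id}\n")
    if attributes_path is not None:
        rows = []
        for e in edges:
            rows.append({
                "source": e.source_id, "relation": e.relation_type,
                "target": e.target_id, "directed": int(e.directed),
                "effect": e.effect, "mechanism": e.mechanism or "",
                "p_value": "" if e.p_value is None else repr(e.p_value),
                "provenance": e.provenance,
                "attributes": json.dumps(e.attributes, sort_keys=True),
            })
        pd.DataFrame(rows).to_csv(attributes_path, sep="\t", index=False)


def read_sif(path, attributes_path=None) -> Network:
    net = Network()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                net.add_node(parts[0])
                continue
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            src, rel, tgt = parts
            net.add_edge(InteractionRecord(
                src, tgt, rel if rel in RELATION_TYPES else "other",
            ))
    if attributes_path is not None:
        df = pd.read_csv(attributes_path, sep="\t", dtype=str).fillna("")
        keyed = {e.key(): e for e in net.edges}
        for row in df.itertuples(index=False):
            rel = row.relation if row.relation in RELATION_TYPES else "other"
            key = (row.source, row.target, rel, "")
            e = keyed.get(key)
            if e is None:
                continue
            e.directed = bool(int(row.directed))
            e.effect = row.effect or "unknown"
            e.mechanism = row.mechanism or None
            e.p_value = float(row.p_value) if row.p_value else None
            e.provenance = row.provenance
            e.attributes = json.loads(row.attributes) if row.attributes else {}
            net._edge_keys.discard(key)
            net._edge_keys.add(e.key())
    return net
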