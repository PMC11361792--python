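"""RNA secondary structure: dot-bracket parsing, graph construction, folding.

A structure graph has one node per base and two typed undirected edge sets:
``adjacent`` edges {i, i+1} along the backbone (phosphodiester bonds) and
``base_pair`` edges {i, j} from stack-matched brackets (hydrogen bonds).
Pseudoknot bracket characters ([, ], {, }) are treated as unpaired with a
warning, since the folding tools this package interoperates with emit nested
structures only.

Structures come from three places: an existing dot-bracket file, an external
folding tool (RNAfold / LinearFold adapter), or the built-in maximum
base-pairing folder (`nussinov_fold`) which needs no external software. The
built-in folder maximizes nested Watson-Crick/wobble pair count with a minimum
hairpin loop, not free energy; it exists so the full pipeline runs
self-contained.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .encoders import node_feature_matrix
from .errors import EnvironmentToolError, StructureMismatchError, StructureParseError
from .records import RnaRecord

logger = logging.getLogger(__name__)

EDGE_ADJACENT = "adjacent"
EDGE_BASE_PAIR = "base_pair"

_PSEUDOKNOT_CHARS = set("[]{}<>")


def parse_dotbracket(db: str) -> list[tuple[int, int]]:
    """Stack-match a dot-bracket string into 0-based (i, j) pairs with i < j.

    Pseudoknot-layer brackets are treated as unpaired (warning); any other
    non-``().`` character is rejected.

    Raises
    ------
    StructureParseError
        On an unmatched bracket (naming its position) or a bad character.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    warned = False
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureParseError(
                    f"unmatched ')' at position {i}", position=i
                )
            pairs.append((stack.pop(), i))
        elif c == ".":
            pass
        elif c in _PSEUDOKNOT_CHARS:
            if not warned:
                logger.warning(
                    "pseudoknot-layer character %r at position %d treated as unpaired",
                    c, i,
                )
                warned = True
        else:
            raise StructureParseError(
                f"invalid dot-bracket character {c!r} at position {i}", position=i
            )
    if stack:
        raise StructureParseError(
            f"unmatched '(' at position {stack[-1]}", position=stack[-1]
        )
    pairs.sort()
    return pairs


@dataclass
class StructureGraph:
    """Graph view of one secondary structure.

    Nodes are 0-based base indices; user-facing interpretation output converts
    to 1-based positions. Edges are stored undirected; `directed_edges`
    provides the doubled representation used for symmetric neighbor
    aggregation in the GNN layers.
    """

    n_nodes: int
    node_features: np.ndarray  # (L, 10)
    adjacent_edges: list[tuple[int, int]]
    pair_edges: list[tuple[int, int]]
    sequence: str = ""

    #: undirected edges in canonical order: adjacent first, then pairs
    edges: list[tuple[int, int]] = field(init=False)
    edge_types: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.edges = list(self.adjacent_edges) + list(self.pair_edges)
        self.edge_types = [EDGE_ADJACENT] * len(self.adjacent_edges) + [
            EDGE_BASE_PAIR
        ] * len(self.pair_edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(src, dst, undirected_edge_id) arrays with every edge doubled."""
        if not self.edges:
            z = np.zeros(0, dtype=np.int64)
            return z, z, z
        e = np.asarray(self.edges, dtype=np.int64)
        src = np.concatenate([e[:, 0], e[:, 1]])
        dst = np.concatenate([e[:, 1], e[:, 0]])
        eid = np.concatenate([np.arange(len(e)), np.arange(len(e))])
        return src, dst, eid


def dotbracket_to_graph(record: RnaRecord, source: str | None = None) -> StructureGraph:
    """Build the two-edge-type structure graph for one record.

    All L nodes are created first; the backbone contributes the L-1
    ``adjacent`` edges and stack-matched brackets contribute the ``base_pair``
    edges. Node features are attached via `node_feature_matrix`.

    Parameters
    ----------
    record : RnaRecord
        Must carry at least one structure.
    source : str, optional
        Which structure source to use; defaults to the first one stored.
    """
    if not record.structures:
        raise StructureMismatchError(f"record {record.id!r} has no structure")
    if source is None:
        source = next(iter(record.structures))
    db = record.structures[source]
    if len(db) != len(record.sequence):
        raise StructureMismatchError(
            f"record {record.id!r}: structure/sequence length mismatch"
        )
    pairs = parse_dotbracket(db)
    L = len(record.sequence)
    adjacent = [(i - 1, i) for i in range(1, L)]
    return StructureGraph(
        n_nodes=L,
        node_features=node_feature_matrix(record.sequence),
        adjacent_edges=adjacent,
        pair_edges=pairs,
        sequence=record.sequence,
    )


# ---------------------------------------------------------------------------
# Built-in maximum base-pairing folder
# ---------------------------------------------------------------------------

_PAIR_OK = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in (("A", "U"), ("G", "C"), ("G", "U")):
    _i, _j = "ACGUN".index(_a), "ACGUN".index(_b)
    _PAIR_OK[_i, _j] = _PAIR_OK[_j, _i] = True


@njit(cache=False)
def _nussinov_dp(codes: np.ndarray, pair_ok: np.ndarray, min_loop: int) -> np.ndarray:
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if pair_ok[codes[k], codes[j]]:
                    left = dp[i, k - 1] if k > i else 0
                    cand = left + dp[k + 1, j - 1] + 1
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


def nussinov_fold(seq: str, min_loop: int = 3) -> str:
    """Nested structure maximizing base-pair count (AU, GC, GU allowed).

    Hairpin loops must span at least `min_loop` unpaired positions. The
    traceback is deterministic: when several pairings attain the optimum, j is
    left unpaired if possible, otherwise j pairs with the smallest eligible k.
    Returns a dot-bracket string; a sequence with no legal pair folds to all
    dots. N pairs with nothing.
    """
    n = len(seq)
    structure = ["."] * n
    if n <= min_loop:
        return "".join(structure)
    codes = np.fromiter(("ACGUN".index(c) for c in seq), dtype=np.int8, count=n)
    dp = _nussinov_dp(codes, _PAIR_OK, min_loop)

    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if _PAIR_OK[codes[k], codes[j]]:
                left = dp[i, k - 1] if k > i else 0
                if left + dp[k + 1, j - 1] + 1 == dp[i, j]:
                    structure[k] = "("
                    structure[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return "".join(structure)


# ---------------------------------------------------------------------------
# External folding tool adapter
# ---------------------------------------------------------------------------

#: invocation templates: the tool reads the raw sequence on stdin and writes
#: the dot-bracket (optionally followed by an energy suffix) to stdout.
_TOOL_COMMANDS = {
    "rnafold": ["RNAfold", "--noPS"],
    "linearfold": ["linearfold"],
}


def _extract_structure_line(output: str, length: int) -> str | None:
    """First line of tool output whose leading token is a dot-bracket string
    of the right length; a trailing free-energy suffix like ``(-1.20)`` is
    stripped."""
    for line in output.splitlines():
        token = line.strip().split(" ")[0].split("\t")[0]
        if len(token) == length and set(token) <= set("().[]{}<>"):
            return token
    return None


def run_external_folder(
    records: list[RnaRecord],
    tool_name: str = "rnafold",
    executable_path: str | None = None,
    source: str | None = None,
) -> list[RnaRecord]:
    """Fold each record with an external tool and attach the structures.

    The tool is invoked once per sequence with the sequence on stdin; the
    first dot-bracket line of its plain-text output is attached under
    `source` (default: the tool name). Order is preserved; nothing is written
    if the executable is missing.

    Raises
    ------
    EnvironmentToolError
        If the executable cannot be found. The built-in `nussinov_fold` is a
        dependency-free alternative.
    """
    if tool_name not in _TOOL_COMMANDS and executable_path is None:
        raise EnvironmentToolError(
            f"unknown folding tool {tool_name!r}; provide executable_path"
        )
    cmd = list(_TOOL_COMMANDS.get(tool_name, [tool_name]))
    if executable_path is not None:
        cmd[0] = executable_path
    resolved = shutil.which(cmd[0])
    if resolved is None:
        raise EnvironmentToolError(
            f"folding executable {cmd[0]!r} not found on PATH; "
            "use the built-in nussinov fold as a fallback"
        )
    cmd[0] = resolved
    if source is None:
        source = tool_name

    for record in records:
        proc = subprocess.run(
            cmd,
            input=record.sequence + "\n",
            capture_output=True,
            text=True,
            check=False,
        )
        structure = _extract_structure_line(proc.stdout, len(record.sequence))
        if proc.returncode != 0 or structure is None:
            logger.warning(
                "folding tool produced no parseable structure for record %s",
                record.id,
            )
            continue
        record.set_structure(source, structure)
    return records
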