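"""Packaged fixtures, gene annotation joins and alteration-profile mapping.

Ships the worked-example network, a three-node cascade, the bladder-cancer
gene annotation table (node, published class, gene symbols, OncoKB role)
and the bladder-cancer cell-line alteration profiles.  Published large
models (e.g. the bladder-cancer "mapk" network) are consumed as
user-supplied ``.bnet`` files; no network fetching is built in.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .network import (
    BnrevertError,
    BooleanNetwork,
    Intervention,
    check_conflict_free,
    control,
    parse_network,
)
from .reversion import ClassificationReport

__all__ = [
    "UnknownFixtureError",
    "AnnotationTable",
    "AlterationProfiles",
    "load_fixture",
    "annotate_classes",
    "map_profile_to_interventions",
]

FIXTURES = ("fig1", "cascade", "table1_annotations", "table2_profiles")


class UnknownFixtureError(BnrevertError):
    """Requested fixture name is not packaged."""


@dataclass
class AnnotationTable:
    """Node -> (published class, gene symbols, OncoKB role) rows.

    ``roles`` are drawn from {"Oncogene", "Tumor suppressor", ""}.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame["node"].duplicated().any():
            raise ValueError("annotation node identifiers must be unique")
        bad = set(self.frame["oncokb"]) - {"Oncogene", "Tumor suppressor", ""}
        if bad:
            raise ValueError(f"unknown OncoKB roles: {bad}")

    @property
    def nodes(self) -> list[str]:
        return list(self.frame["node"])

    def published_classes(self) -> dict[str, str]:
        return dict(zip(self.frame["node"], self.frame["node_class"]))

    def role_of(self, node: str) -> str:
        rows = self.frame[self.frame["node"] == node]
        return rows["oncokb"].iloc[0] if len(rows) else ""

    def gene_to_node(self) -> dict[str, str]:
        """Many-to-one gene-symbol -> node map from the genes column."""
        out: dict[str, str] = {}
        for _, row in self.frame.iterrows():
            for gene in str(row["genes"]).split():
                if gene and gene != "nan":
                    out.setdefault(gene, row["node"])
        return out


@dataclass
class AlterationProfiles:
    """Per cell line: gene -> GOF/LOF alteration calls."""

    frame: pd.DataFrame

    def cell_lines(self) -> list[str]:
        return sorted(self.frame["cell_line"].unique())

    def profile(self, cell_line: str) -> dict[str, str]:
        rows = self.frame[self.frame["cell_line"] == cell_line]
        if rows.empty:
            raise KeyError(f"unknown cell line {cell_line!r}")
        return dict(zip(rows["gene"], rows["alteration"]))


def _data_path(name: str):
    return importlib.resources.files("bnrevert") / "data" / name


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``fig1`` and ``cascade`` return a :class:`BooleanNetwork`;
    ``table1_annotations`` an :class:`AnnotationTable`;
    ``table2_profiles`` an :class:`AlterationProfiles`.
    """
    if name == "fig1" or name == "cascade":
        text = _data_path(f"{name}.bnet").read_text()
        return parse_network(text)
    if name == "table1_annotations":
        with importlib.resources.as_file(_data_path("table1_annotations.csv")) as p:
            frame = pd.read_csv(p, keep_default_na=False)
        return AnnotationTable(frame)
    if name == "table2_profiles":
        with importlib.resources.as_file(_data_path("table2_profiles.csv")) as p:
            frame = pd.read_csv(p)
        return AlterationProfiles(frame)
    raise UnknownFixtureError(f"unknown fixture {name!r}; available: {FIXTURES}")


def annotate_classes(
    report: ClassificationReport | Mapping[str, str], table: AnnotationTable
) -> pd.DataFrame:
    """Per class: total node count and count with a non-empty OncoKB role.

    ``report`` may be a classification report or a plain node -> class
    mapping (e.g. the published classes of the annotation table itself).
    Nodes missing from the annotation table are listed in the returned
    frame's ``unmatched`` attribute rather than raising.
    """
    classes = report.classes if isinstance(report, ClassificationReport) else dict(report)
    roles = dict(zip(table.frame["node"], table.frame["oncokb"]))
    unmatched = sorted(n for n in classes if n not in roles)
    rows = []
    for cls in ("C0", "C1", "C2", "C3"):
        members = [n for n, c in classes.items() if c == cls]
        annotated = sum(1 for n in members if roles.get(n, "") != "")
        rows.append({"class": cls, "total": len(members), "annotated": annotated})
    frame = pd.DataFrame(rows).set_index("class")
    frame.attrs["unmatched"] = unmatched
    return frame


def map_profile_to_interventions(
    profile: Mapping[str, str],
    table: AnnotationTable,
    net: BooleanNetwork,
) -> tuple[list[Intervention], list[str]]:
    """Map a gene -> GOF/LOF profile onto network-node interventions.

    GOF alterations fix the node to 1, LOF to 0, using the annotation
    table's gene-symbol column to resolve gene names to network nodes.
    Genes that resolve to no network node are returned as skipped
    warnings, not errors; two genes mapping the same node to different
    values raise :class:`ConflictingInterventionError`.
    """
    gene_map = table.gene_to_node()
    interventions: list[Intervention] = []
    skipped: list[str] = []
    for gene, alteration in profile.items():
        if alteration not in ("GOF", "LOF"):
            raise ValueError(f"alteration for {gene!r} must be GOF or LOF")
        node = gene_map.get(gene)
        if node is None or node not in net.index:
            skipped.append(gene)
            continue
        interventions.append(control(node, 1 if alteration == "GOF" else 0))
    check_conflict_free(interventions)
    # dedupe identical fixations (two genes of one node, same direction)
    seen: set[tuple[str, int]] = set()
    unique = []
    for iv in interventions:
        if (iv.node, iv.value) not in seen:
            seen.add((iv.node, iv.value))
            unique.append(iv)
    return unique, skipped
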