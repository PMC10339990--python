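"""Readers and writers for the package's plain-text formats, plus fixtures.

Formats
-------
Karyogram TSV (one file per taxon)
    ``#``-prefixed header comments carry the taxon label, inert annotations
    (NOR position, heterochromatin notes) and free-text provenance, then a
    tab-separated table ``rank rl_mean rl_sd ci_mean ci_sd morph`` with
    ``NA`` for pairs whose centromeric index was not measured.

Tip-state TSV
    ``taxon m sm st t`` haploid counts per morphology class; tips without
    karyotype data are listed with ``?`` in every count column so the tree
    and the state file stay congruent.

Measurement TSV
    ``cell_id rank length short_arm_length`` long table, arbitrary length
    units (only ratios are used downstream).

Cost config
    Flat ``key: value`` text with the event costs and search bounds.

Tree
    Rooted binary Newick; branch lengths are ignored (parsimony is
    length-free) and polytomies are rejected.

The packaged ``fixtures/`` directory transcribes the published karyotype
measurements for the four Blaesodactylus taxa, the literature karyotype
states for Geckolepis typica and the two Homopholis species, the specimen
table, the study phylogeny, and the default event-cost configuration; see
``fixtures/MANIFEST.tsv`` for per-file provenance.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd

from .karyotype_core import (
    ChromosomePairRecord,
    Karyogram,
    KaryotypeState,
    MorphClass,
)
from .rearrangement_engine import EventModel

__all__ = [
    "read_karyogram",
    "write_karyogram",
    "read_tip_states",
    "write_tip_states",
    "read_tree",
    "read_specimens",
    "read_costs",
    "write_costs",
    "read_measurements",
    "write_measurements",
    "fixture_path",
    "load_fixture_karyograms",
    "load_case_study_inputs",
    "FIXTURE_KARYOGRAMS",
]

logger = logging.getLogger(__name__)

FIXTURE_KARYOGRAMS = ("antongilensis", "sakalavaA", "sakalavaB", "boivini")


def _fmt(v: float | None) -> str:
    if v is None:
        return "NA"
    if abs(v - round(v, 1)) < 1e-12:
        return f"{v:.1f}"
    return f"{v:.6g}"


# ---------------------------------------------------------------------------
# karyogram TSV
# ---------------------------------------------------------------------------

_KARYOGRAM_HEADER = "rank\trl_mean\trl_sd\tci_mean\tci_sd\tmorph"


def read_karyogram(path: str | Path) -> Karyogram:
    """Parse a karyogram TSV; validates all karyogram invariants."""
    path = Path(path)
    taxon = path.stem
    annotations: dict[str, str] = {}
    provenance: list[str] = []
    pairs: list[ChromosomePairRecord] = []
    seen_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("taxon:"):
                    taxon = body.split(":", 1)[1].strip()
                elif body.startswith("annotation "):
                    key, _, val = body[len("annotation "):].partition(":")
                    annotations[key.strip()] = val.strip()
                else:
                    provenance.append(body)
                continue
            if not seen_header:
                if line != _KARYOGRAM_HEADER:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {_KARYOGRAM_HEADER!r}"
                    )
                seen_header = True
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                rank = int(fields[0])
                rl_mean, rl_sd = float(fields[1]), float(fields[2])
                ci_mean = None if fields[3] == "NA" else float(fields[3])
                ci_sd = None if fields[4] == "NA" else float(fields[4])
                morph = MorphClass.parse(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if any(r.rank == rank for r in pairs):
                raise ValueError(f"{path}:{lineno}: duplicate rank {rank}")
            pairs.append(
                ChromosomePairRecord(
                    rank=rank,
                    rl_mean=rl_mean,
                    rl_sd=rl_sd,
                    ci_mean=ci_mean,
                    ci_sd=ci_sd,
                    morph=morph,
                )
            )
    if not seen_header:
        raise ValueError(f"{path}: no data header found")
    return Karyogram(
        taxon=taxon, pairs=pairs, annotations=annotations, provenance=provenance
    )


def write_karyogram(k: Karyogram, path: str | Path) -> None:
    """Write a karyogram in canonical TSV form (round-trips exactly)."""
    lines = [f"# taxon: {k.taxon}"]
    for key, val in k.annotations.items():
        lines.append(f"# annotation {key}: {val}")
    for note in k.provenance:
        lines.append(f"# {note}")
    lines.append(_KARYOGRAM_HEADER)
    for p in k.pairs:
        lines.append(
            "\t".join(
                [
                    str(p.rank),
                    _fmt(p.rl_mean),
                    _fmt(p.rl_sd),
                    _fmt(p.ci_mean),
                    _fmt(p.ci_sd),
                    p.morph.value,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tip states
# ---------------------------------------------------------------------------

_STATES_HEADER = "taxon\tm\tsm\tst\tt"


class TipStates(dict):
    """Tip label -> state (or ``None``) mapping that keeps file comments."""

    def __init__(self, *args, provenance: list[str] | None = None, **kwargs):
        super().__init__(*args, **kwargs)
        self.provenance: list[str] = provenance or []


def read_tip_states(path: str | Path) -> TipStates:
    """Parse a tip-state TSV; ``?`` rows become unknown (``None``)."""
    path = Path(path)
    out = TipStates()
    seen_header = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                out.provenance.append(line.lstrip("#").strip())
                continue
            if not seen_header:
                if line != _STATES_HEADER:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {_STATES_HEADER!r}"
                    )
                seen_header = True
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 fields, got {len(fields)}"
                )
            taxon = fields[0]
            if taxon in out:
                raise ValueError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
            if all(f == "?" for f in fields[1:]):
                out[taxon] = None
                continue
            try:
                counts = [int(f) for f in fields[1:]]
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: counts must be integers or all '?'"
                ) from None
            if any(c < 0 for c in counts):
                raise ValueError(f"{path}:{lineno}: negative count")
            out[taxon] = KaryotypeState(*counts)
    if not seen_header or not out:
        raise ValueError(f"{path}: no tip states found")
    return out


def write_tip_states(
    states: Mapping[str, KaryotypeState | None],
    path: str | Path,
    provenance: list[str] | None = None,
) -> None:
    if provenance is None:
        provenance = getattr(states, "provenance", [])
    lines = [f"# {note}" for note in provenance]
    lines.append(_STATES_HEADER)
    for taxon, s in states.items():
        if s is None:
            lines.append(f"{taxon}\t?\t?\t?\t?")
        else:
            lines.append(f"{taxon}\t{s.m}\t{s.sm}\t{s.st}\t{s.t}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tree / specimens / costs / measurements
# ---------------------------------------------------------------------------


def read_tree(path_or_string: str | Path) -> dendropy.Tree:
    """Read a rooted binary Newick tree; branch lengths are ignored.

    Accepts a path or a literal Newick string.
    """
    text = str(path_or_string)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"invalid Newick tree: {exc}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tree has duplicate tip labels")
    for nd in tree.preorder_node_iter():
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            raise ValueError(
                "tree must be binary and rooted; found a node with "
                f"{len(kids)} children (polytomies are rejected)"
            )
    return tree


def read_specimens(path: str | Path) -> pd.DataFrame:
    """Specimen table TSV with columns species, specimen, locality, sex."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["species", "specimen", "locality", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"specimen table missing columns: {missing}")
    if df.empty:
        logger.warning("specimen table %s has no records", path)
    return df


def read_costs(path: str | Path) -> EventModel:
    """Flat ``key: value`` event-cost configuration -> :class:`EventModel`."""
    kwargs: dict = {}
    keymap = {
        "fusion": ("fusion_cost", float),
        "fission": ("fission_cost", float),
        "inversion": ("inversion_cost", float),
        "repositioning": ("repositioning_cost", float),
        "fusion_target": ("fusion_target", MorphClass.parse),
        "state_radius": ("state_radius", int),
        "max_n": ("max_n", int),
    }
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, val = line.partition(":")
            if not sep:
                raise ValueError(f"{path}:{lineno}: expected 'key: value'")
            key = key.strip()
            if key not in keymap:
                raise ValueError(f"{path}:{lineno}: unknown cost key {key!r}")
            name, conv = keymap[key]
            kwargs[name] = conv(val.strip())
    return EventModel(**kwargs)


def write_costs(model: EventModel, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(
            [
                f"fusion: {model.fusion_cost:g}",
                f"fission: {model.fission_cost:g}",
                f"inversion: {model.inversion_cost:g}",
                f"repositioning: {model.repositioning_cost:g}",
                f"fusion_target: {model.fusion_target.value}",
                f"state_radius: {model.state_radius}",
                f"max_n: {model.max_n}",
            ]
        )
        + "\n"
    )


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Per-cell chromosome length table TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"cell_id", "rank", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture file (e.g. ``'tree.nwk'``)."""
    p = resources.files("karyoevol") / "fixtures" / name
    return Path(str(p))


def load_fixture_karyograms() -> dict[str, Karyogram]:
    """The four measured karyograms, keyed by tree tip label."""
    return {
        name: read_karyogram(fixture_path(f"{name}.tsv"))
        for name in FIXTURE_KARYOGRAMS
    }


def load_case_study_inputs():
    """Everything the case study needs: tree, karyograms, states, costs.

    Returns ``(tree, karyograms, literature_states, model)``. The
    literature state file also carries explicit unknown rows for the tips
    without karyotype data.
    """
    tree = read_tree(fixture_path("tree.nwk"))
    karyograms = load_fixture_karyograms()
    literature_states = read_tip_states(fixture_path("literature_states.tsv"))
    model = read_costs(fixture_path("costs.txt"))
    return tree, karyograms, literature_states, model
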