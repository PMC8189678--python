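"""Chain selection: resolution filtering and mapping inference.

The 3D side of the dataset starts from three tables: a chain list with
resolutions, a partition of those chains into redundancy *equivalence
classes* (replicas of the same molecule solved in different experiments),
and a table of direct chain-to-family mappings with residue ranges.  Many
chains lack a direct mapping but sit in a class where another chain has
one; such mappings are propagated to every classmate.  A chain mapped to
several families is copied once per family, each copy truncated to the
mapped residue range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .structure_io import RnaChain

logger = logging.getLogger(__name__)

ChainKey = tuple[str, str]  # (structure_id, chain_id)


@dataclass(frozen=True)
class ChainEntry:
    structure_id: str
    chain_id: str
    resolution: float | None  # Angstrom; None = unknown (e.g. NMR)

    @property
    def key(self) -> ChainKey:
        return (self.structure_id, self.chain_id)


@dataclass(frozen=True)
class FamilyMapping:
    structure_id: str
    chain_id: str
    family: str
    start: int  # 1-based, closed range
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid mapping range [{self.start}, {self.end}]")


@dataclass
class SelectionTables:
    """Chain list + equivalence-class partition + family mappings."""

    chains: list[ChainEntry]
    classes: list[list[ChainKey]]
    mappings: list[FamilyMapping]

    def validate(self) -> None:
        keys = [ch.key for ch in self.chains]
        seen: set[ChainKey] = set()
        for cls in self.classes:
            for key in cls:
                if key in seen:
                    raise ValueError(f"chain {key} appears in two equivalence classes")
                seen.add(key)
        missing = set(keys) - seen
        if missing:
            raise ValueError(f"chains missing from the class partition: {sorted(missing)}")


@dataclass(frozen=True)
class SelectedChain:
    """A chain retained for the dataset, with its family and residue range."""

    structure_id: str
    chain_id: str
    resolution: float | None
    family: str
    start: int
    end: int
    inferred: bool  # True when the mapping came through an equivalence class

    @property
    def key(self) -> ChainKey:
        return (self.structure_id, self.chain_id)


def filter_by_resolution(
    chains: list[ChainEntry], threshold: float
) -> list[ChainEntry]:
    """Keep chains whose known resolution is <= threshold (Angstrom).

    Chains with unknown resolution (NMR and similar) are excluded.
    """
    if threshold <= 0:
        raise ValueError("resolution threshold must be positive")
    return [c for c in chains if c.resolution is not None and c.resolution <= threshold]


def infer_mappings(tables: SelectionTables) -> list[SelectedChain]:
    """Resolve every chain's family mappings, propagating through classes.

    Directly mapped chains keep their own mappings.  A chain without any
    direct mapping inherits every (family, range) mapped to any classmate;
    when several classmates map the same family with different ranges, the
    widest range wins.  A chain mapped to k families yields k copies.
    Chains with neither direct nor inferable mappings are dropped; mappings
    that reference chains absent from the chain list are ignored with a
    warning.  Output order is canonical (structure, chain, family),
    independent of input row order.
    """
    tables.validate()
    by_key = {c.key: c for c in tables.chains}
    direct: dict[ChainKey, dict[str, tuple[int, int]]] = {}
    for m in tables.mappings:
        key = (m.structure_id, m.chain_id)
        if key not in by_key:
            logger.warning("mapping references unknown chain %s, ignored", key)
            continue
        fams = direct.setdefault(key, {})
        prev = fams.get(m.family)
        rng = (m.start, m.end)
        if prev is None or (rng[1] - rng[0]) > (prev[1] - prev[0]):
            fams[m.family] = rng

    class_of: dict[ChainKey, int] = {}
    for ci, members in enumerate(tables.classes):
        for key in members:
            class_of[key] = ci

    out: list[SelectedChain] = []
    for chain in tables.chains:
        if chain.key in direct:
            fams = direct[chain.key]
            inferred = False
        else:
            # union of classmates' direct mappings, widest range per family
            fams = {}
            ci = class_of.get(chain.key)
            if ci is not None:
                for mate in tables.classes[ci]:
                    for fam, rng in direct.get(mate, {}).items():
                        prev = fams.get(fam)
                        if prev is None or (rng[1] - rng[0]) > (prev[1] - prev[0]):
                            fams[fam] = rng
            inferred = True
        for fam, (start, end) in sorted(fams.items()):
            out.append(
                SelectedChain(
                    structure_id=chain.structure_id,
                    chain_id=chain.chain_id,
                    resolution=chain.resolution,
                    family=fam,
                    start=start,
                    end=end,
                    inferred=inferred,
                )
            )
    out.sort(key=lambda s: (s.structure_id, s.chain_id, s.family))
    return out


def select_chains(
    tables: SelectionTables, resolution_threshold: float = 4.0
) -> list[SelectedChain]:
    """Resolution filter then mapping inference, the full selection stage."""
    kept = filter_by_resolution(tables.chains, resolution_threshold)
    subset = SelectionTables(
        chains=kept,
        classes=[
            [k for k in cls if k in {c.key for c in kept}] for cls in tables.classes
        ],
        mappings=tables.mappings,
    )
    subset.classes = [cls for cls in subset.classes if cls]
    return infer_mappings(subset)


def truncate_to_mapping(chain: RnaChain, selected: SelectedChain) -> RnaChain:
    """Copy a chain truncated to its mapping's residue range.

    The range is clipped to the chain's actual length (family-relative
    ranges can exceed it, e.g. when inherited from a longer classmate);
    clipping is logged.  Residues are renumbered 1..L' and the mapping is
    recorded on the copy.
    """
    start, end = selected.start, selected.end
    clipped_end = min(end, len(chain.residues))
    clipped_start = max(1, start)
    if (clipped_start, clipped_end) != (start, end):
        logger.info(
            "mapping range [%d, %d] clipped to [%d, %d] for %s:%s",
            start, end, clipped_start, clipped_end,
            chain.structure_id, chain.chain_id,
        )
    kept = chain.residues[clipped_start - 1 : clipped_end]
    renumbered = [replace(r, index=i + 1) for i, r in enumerate(kept)]
    return replace(
        chain,
        residues=renumbered,
        mapping=(selected.family, (clipped_start, clipped_end)),
    )


# ---------------------------------------------------------------------------
# CSV round-trip for the three tables

def write_selection_tables(tables: SelectionTables, chains_csv, classes_csv, mappings_csv) -> None:
    pd.DataFrame(
        [
            {
                "structure_id": c.structure_id,
                "chain_id": c.chain_id,
                "resolution": c.resolution,
            }
            for c in tables.chains
        ]
    ).to_csv(chains_csv, index=False)
    pd.DataFrame(
        [
            {"class_id": ci, "structure_id": sid, "chain_id": cid}
            for ci, members in enumerate(tables.classes)
            for sid, cid in members
        ]
    ).to_csv(classes_csv, index=False)
    pd.DataFrame(
        [
            {
                "structure_id": m.structure_id,
                "chain_id": m.chain_id,
                "family": m.family,
                "start": m.start,
                "end": m.end,
            }
            for m in tables.mappings
        ]
    ).to_csv(mappings_csv, index=False)


def read_selection_tables(chains_csv, classes_csv, mappings_csv) -> SelectionTables:
    chains_df = pd.read_csv(chains_csv)
    chains = [
        ChainEntry(
            str(r.structure_id),
            str(r.chain_id),
            None if pd.isna(r.resolution) else float(r.resolution),
        )
        for r in chains_df.itertuples()
    ]
    classes_df = pd.read_csv(classes_csv)
    classes: list[list[ChainKey]] = []
    if len(classes_df):
        for _, grp in classes_df.groupby("class_id", sort=True):
            classes.append([(str(r.structure_id), str(r.chain_id)) for r in grp.itertuples()])
    mappings_df = pd.read_csv(mappings_csv)
    mappings = [
        FamilyMapping(
            str(r.structure_id), str(r.chain_id), str(r.family), int(r.start), int(r.end)
        )
        for r in mappings_df.itertuples()
    ]
    return SelectionTables(chains=chains, classes=classes, mappings=mappings)
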