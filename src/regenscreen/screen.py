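"""Orthogroup construction and the conserved-in-WBR / lost-in-LRA screen.

The core inference: genes forming mutual-best-hit (MBH) cliques across all
whole-body-regenerating (WBR) species are orthogroups; an orthogroup is a
candidate regeneration gene family iff no member has any similarity hit at
E <= 1e-4 in any low-regenerative-ability (LRA) proteome, its absence is
confirmed against a second (CONFIRM) proteome panel, and its orthologs in
high-regenerative-ability (HRA) species are collected by mutual best hit at
raw score > 100 into a presence/absence matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .similarity import (
    MbhPair,
    Proteome,
    ScoringScheme,
    SimilarityHit,
    find_any_hit,
    mutual_best_from_matrix,
    pairwise_score_matrix,
    select_longest_isoform,
)


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and species-class lists for the screen."""

    wbr: tuple[str, ...]
    hra: tuple[str, ...] = ()
    lra: tuple[str, ...] = ()
    confirm: tuple[str, ...] = ()
    evalue_max_loss: float = 1e-4
    score_min_hra: int = 100
    grouping: str = "clique"  # or "components"

    def __post_init__(self) -> None:
        if self.evalue_max_loss <= 0:
            raise ScreenError("evalue_max_loss must be positive")
        if self.score_min_hra <= 0:
            raise ScreenError("score_min_hra must be positive")
        if self.grouping not in ("clique", "components"):
            raise ScreenError(f"unknown grouping rule {self.grouping!r}")
        lists = [self.wbr, self.hra, self.lra, self.confirm]
        flat = [s for lst in lists for s in lst]
        if len(set(flat)) != len(flat):
            raise ScreenError("species class lists must be disjoint")
        if not self.wbr:
            raise ScreenError("at least one WBR species required")

    @property
    def anchor_species(self) -> str:
        return self.wbr[0]


@dataclass(frozen=True)
class Orthogroup:
    """A cross-species gene set; the anchor is the first WBR species' member."""

    group_id: str
    members: frozenset[tuple[str, str]]  # (species_id, gene_id)
    anchor: tuple[str, str]

    def member_in(self, species_id: str) -> str | None:
        for sp, gene in self.members:
            if sp == species_id:
                return gene
        return None


def _mbh_lookup(
    mbh: Mapping[tuple[str, str], Sequence[MbhPair]], sa: str, sb: str
) -> dict[str, str] | None:
    """Partner map gene(sa) -> gene(sb) from whichever key orientation exists."""
    if (sa, sb) in mbh:
        return {p.gene_a: p.gene_b for p in mbh[(sa, sb)]}
    if (sb, sa) in mbh:
        return {p.gene_b: p.gene_a for p in mbh[(sb, sa)]}
    return None


def build_wbr_orthogroups(
    mbh: Mapping[tuple[str, str], Sequence[MbhPair]],
    wbr_species: Sequence[str],
    grouping: str = "clique",
) -> list[Orthogroup]:
    """Orthogroups from per-pair MBH lists across the WBR species.

    In the default "clique" mode a group is emitted iff one gene per WBR
    species forms a complete MBH clique (triangle closure for three species).
    "components" mode instead takes connected components of the MBH graph and
    keeps those with exactly one member per WBR species (sensitivity
    alternative; the two agree whenever MBH edges are transitive).
    """
    wbr = list(wbr_species)
    partner: dict[tuple[str, str], dict[str, str]] = {}
    for i, sa in enumerate(wbr):
        for sb in wbr[i + 1:]:
            look = _mbh_lookup(mbh, sa, sb)
            if look is None:
                raise ScreenError(f"missing MBH list for WBR pair ({sa}, {sb})")
            partner[(sa, sb)] = look
            partner[(sb, sa)] = {v: k for k, v in look.items()}

    groups: list[tuple[tuple[str, str], frozenset[tuple[str, str]]]] = []
    if grouping == "clique":
        anchor_sp = wbr[0]
        for g0 in sorted(partner[(anchor_sp, wbr[1])] if len(wbr) > 1 else {}):
            members = {anchor_sp: g0}
            ok = True
            for sb in wbr[1:]:
                p = partner[(anchor_sp, sb)].get(g0)
                if p is None:
                    ok = False
                    break
                members[sb] = p
            if not ok:
                continue
            for i, sa in enumerate(wbr):
                for sb in wbr[i + 1:]:
                    if partner[(sa, sb)].get(members[sa]) != members[sb]:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                groups.append(
                    ((anchor_sp, g0), frozenset((sp, g) for sp, g in members.items()))
                )
    else:  # connected components of the MBH graph
        adj: dict[tuple[str, str], set[tuple[str, str]]] = {}
        for (sa, sb), look in partner.items():
            for ga, gb in look.items():
                adj.setdefault((sa, ga), set()).add((sb, gb))
                adj.setdefault((sb, gb), set()).add((sa, ga))
        seen: set[tuple[str, str]] = set()
        for node in sorted(adj):
            if node in seen:
                continue
            comp = {node}
            stack = [node]
            while stack:
                cur = stack.pop()
                for nxt in adj[cur]:
                    if nxt not in comp:
                        comp.add(nxt)
                        stack.append(nxt)
            seen |= comp
            per_species: dict[str, list[str]] = {}
            for sp, g in comp:
                per_species.setdefault(sp, []).append(g)
            if set(per_species) == set(wbr) and all(len(v) == 1 for v in per_species.values()):
                anchor = (wbr[0], per_species[wbr[0]][0])
                groups.append((anchor, frozenset(comp)))

    groups.sort(key=lambda t: t[0][1])
    out = []
    used: set[tuple[str, str]] = set()
    for idx, (anchor, members) in enumerate(groups, start=1):
        if members & used:  # a gene appears in at most one group
            continue
        used |= members
        out.append(Orthogroup(group_id=f"OG{idx:04d}", members=members, anchor=anchor))
    return out


def filter_lost_in_lra(
    groups: Sequence[Orthogroup],
    hits_wbr_to_lra: Iterable[SimilarityHit],
    config: ScreenConfig,
) -> list[Orthogroup]:
    """Drop every group with ANY member hitting ANY LRA gene at E <= threshold."""
    member_to_group: dict[tuple[str, str], str] = {}
    for g in groups:
        for m in g.members:
            member_to_group[m] = g.group_id
    lra = set(config.lra)
    removed: set[str] = set()
    for h in hits_wbr_to_lra:
        if h.subject_species not in lra or h.evalue > config.evalue_max_loss:
            continue
        gid = member_to_group.get((h.query_species, h.query_gene))
        if gid is not None:
            removed.add(gid)
    return [g for g in groups if g.group_id not in removed]


def _scan_groups_for_hits(
    groups: Sequence[Orthogroup],
    wbr_proteomes: Mapping[str, Proteome],
    panel: Mapping[str, Proteome],
    scheme: ScoringScheme,
    evalue_max: float,
) -> list[SimilarityHit]:
    """First disqualifying hit per group against a proteome panel.

    Early-exit: scanning a group stops at its first qualifying hit, which is
    sufficient for any-hit loss semantics and is what makes the screen fast
    (groups with a true LRA ortholog disqualify almost immediately; only
    genuinely absent families pay for a full scan).
    """
    hits: list[SimilarityHit] = []
    for g in groups:
        found = False
        for sp, gene in sorted(g.members):
            if sp not in wbr_proteomes:
                continue
            seq = wbr_proteomes[sp].gene_sequence(gene)
            for panel_sp in sorted(panel):
                res = find_any_hit(seq, panel[panel_sp], scheme, evalue_max)
                if res is not None:
                    sgene, score, evalue = res
                    hits.append(SimilarityHit(sp, gene, panel_sp, sgene, score, evalue))
                    found = True
                    break
            if found:
                break
    return hits


def confirm_absence(
    groups: Sequence[Orthogroup],
    wbr_proteomes: Mapping[str, Proteome],
    confirm_proteomes: Mapping[str, Proteome],
    config: ScreenConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[list[Orthogroup], pd.DataFrame]:
    """Second screening against the CONFIRM panel; returns survivors + audit.

    The CONFIRM panel is the local, reproducible stand-in for a live
    database-wide absence check. An empty panel passes groups through with a
    warning. The audit log records every removing hit.
    """
    audit_cols = ["group_id", "query_species", "query_gene",
                  "subject_species", "subject_gene", "score", "evalue"]
    if not confirm_proteomes:
        warnings.warn("empty CONFIRM panel: groups passed through unchanged")
        return list(groups), pd.DataFrame(columns=audit_cols)
    hits = _scan_groups_for_hits(
        groups, wbr_proteomes, confirm_proteomes, scheme, config.evalue_max_loss
    )
    member_to_group = {m: g.group_id for g in groups for m in g.members}
    rows = [
        (member_to_group[(h.query_species, h.query_gene)],
         h.query_species, h.query_gene, h.subject_species, h.subject_gene,
         h.score, h.evalue)
        for h in hits
    ]
    audit = pd.DataFrame(rows, columns=audit_cols)
    removed = set(audit["group_id"])
    return [g for g in groups if g.group_id not in removed], audit


# ---------------------------------------------------------------------------
# presence/absence matrix


@dataclass
class PresenceAbsenceMatrix:
    """Orthogroups x species 0/1 matrix with per-species regeneration class."""

    data: pd.DataFrame  # index: group_id, columns: species_id, values 0/1
    reg_class: pd.Series  # species_id -> class

    def validate(self) -> "PresenceAbsenceMatrix":
        if not set(self.data.columns) <= set(self.reg_class.index):
            raise ScreenError("matrix columns without a regeneration class")
        wbr = [c for c in self.data.columns if self.reg_class[c] == "WBR"]
        other = [c for c in self.data.columns if self.reg_class[c] in ("LRA", "CONFIRM")]
        if len(self.data) and wbr and not (self.data[wbr] == 1).all().all():
            raise ScreenError("retained rows must be present in every WBR species")
        if len(self.data) and other and not (self.data[other] == 0).all().all():
            raise ScreenError("retained rows must be absent from LRA/CONFIRM species")
        return self

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.columns = pd.MultiIndex.from_arrays(
            [out.columns, [self.reg_class[c] for c in out.columns]],
            names=["species_id", "reg_class"],
        )
        flat = out.copy()
        flat.columns = [f"{s}:{c}" for s, c in out.columns]
        flat.rename_axis("group_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        species, classes = zip(*(c.split(":", 1) for c in df.columns))
        df.columns = list(species)
        return cls(df, pd.Series(classes, index=list(species)))


def collect_hra_orthologs(
    groups: Sequence[Orthogroup],
    proteomes: Mapping[str, Proteome],
    config: ScreenConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> PresenceAbsenceMatrix:
    """HRA presence by mutual best hit (anchor species queries, score > threshold).

    ``proteomes`` must contain the anchor (first WBR) species and every HRA
    species, isoform-reduced. WBR columns are filled as present and
    LRA/CONFIRM columns as absent for completeness.
    """
    anchor_sp = config.anchor_species
    if anchor_sp not in proteomes:
        raise ScreenError(f"anchor species {anchor_sp!r} proteome missing")
    anchors: dict[str, str] = {}
    for g in groups:
        a = g.member_in(anchor_sp)
        if a is None:
            raise ScreenError(f"group {g.group_id} has no member in anchor species")
        anchors[g.group_id] = a

    present_by_species: dict[str, dict[str, int]] = {}
    for hra_sp in config.hra:
        if hra_sp not in proteomes:
            raise ScreenError(f"HRA species {hra_sp!r} proteome missing")
        pairs = mutual_best_from_matrix(proteomes[anchor_sp], proteomes[hra_sp], scheme)
        mbh_score = {p.gene_a: p.score for p in pairs}
        present_by_species[hra_sp] = {
            gid: int(mbh_score.get(anchor, 0) > config.score_min_hra)
            for gid, anchor in anchors.items()
        }

    gids = [g.group_id for g in groups]
    columns: dict[str, list[int]] = {}
    classes: dict[str, str] = {}
    for sp in config.wbr:
        columns[sp] = [1] * len(gids)
        classes[sp] = "WBR"
    for sp in config.hra:
        columns[sp] = [present_by_species[sp][gid] for gid in gids]
        classes[sp] = "HRA"
    for sp in config.lra:
        columns[sp] = [0] * len(gids)
        classes[sp] = "LRA"
    for sp in config.confirm:
        columns[sp] = [0] * len(gids)
        classes[sp] = "CONFIRM"
    data = pd.DataFrame(columns, index=gids)
    return PresenceAbsenceMatrix(data, pd.Series(classes)).validate()


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class ScreenResult:
    initial_groups: list[Orthogroup]
    after_lra: list[Orthogroup]
    confirmed: list[Orthogroup]
    matrix: PresenceAbsenceMatrix
    audit: pd.DataFrame
    lra_hits: list[SimilarityHit] = field(default_factory=list)

    @property
    def candidate_families(self) -> set[str]:
        """Anchor gene ids of confirmed groups (family ids in synthetic data)."""
        return {g.anchor[1] for g in self.confirmed}

    def write_outputs(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, groups in (
            ("orthogroups_initial.tsv", self.initial_groups),
            ("orthogroups_lost_in_lra.tsv", self.after_lra),
            ("candidates.tsv", self.confirmed),
        ):
            rows = [
                (g.group_id, sp, gene)
                for g in groups
                for sp, gene in sorted(g.members)
            ]
            path = outdir / name
            pd.DataFrame(rows, columns=["group_id", "species_id", "gene_id"]).to_csv(
                path, sep="\t", index=False
            )
            paths.append(path)
        mpath = outdir / "presence_absence.tsv"
        self.matrix.write_tsv(mpath)
        paths.append(mpath)
        apath = outdir / "confirm_audit.tsv"
        self.audit.to_csv(apath, sep="\t", index=False)
        paths.append(apath)
        return paths


def run_screen(
    proteomes: Mapping[str, Proteome],
    config: ScreenConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> ScreenResult:
    """Run the full screen: MBH cliques -> LRA loss filter -> confirm -> matrix."""
    for sp in (*config.wbr, *config.hra, *config.lra, *config.confirm):
        if sp not in proteomes:
            raise ScreenError(f"species {sp!r} listed in config but proteome missing")
    reduced = {sp: select_longest_isoform(p) for sp, p in proteomes.items()}

    mbh: dict[tuple[str, str], list[MbhPair]] = {}
    for i, sa in enumerate(config.wbr):
        for sb in config.wbr[i + 1:]:
            mbh[(sa, sb)] = mutual_best_from_matrix(reduced[sa], reduced[sb], scheme)
    initial = build_wbr_orthogroups(mbh, config.wbr, config.grouping)

    wbr_prot = {sp: reduced[sp] for sp in config.wbr}
    lra_panel = {sp: reduced[sp] for sp in config.lra}
    lra_hits = _scan_groups_for_hits(
        initial, wbr_prot, lra_panel, scheme, config.evalue_max_loss
    )
    after_lra = filter_lost_in_lra(initial, lra_hits, config)

    confirm_panel = {sp: reduced[sp] for sp in config.confirm}
    confirmed, audit = confirm_absence(after_lra, wbr_prot, confirm_panel, config, scheme)

    matrix = collect_hra_orthologs(confirmed, reduced, config, scheme)
    return ScreenResult(initial, after_lra, confirmed, matrix, audit, lra_hits)
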