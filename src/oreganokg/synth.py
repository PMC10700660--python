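"""Synthetic source suite with known ground truth.

Generates toy dumps for the seven knowledge sources (drug and protein
sources as XML-like records, the pharmacogenomic / side-effect / pathway /
natural-compound / phenotype-annotation sources as row-typed TSV tables, the
phenotype hierarchy as OBO) plus the two pivot mapping files, so the whole
ETL and the link-prediction layer are testable without any download.

The generator plants:

* an identity partition — the same underlying entity appears in several
  sources under different local identifiers, carrying a shared hub
  cross-reference with probability ``hub_density`` (plus spurious
  cross-references at rate ``xref_noise``);
* the pivot topology — phenotype-source diseases reach OMIM codes and the
  pharmacogenomic source only through the concept pivot (an indirect
  mapping), never directly;
* block-structured relations — compounds, targets, genes, diseases,
  phenotypes and annotation vocabularies are assigned to latent blocks and
  edges are drawn preferentially within a block, so held-out within-block
  edges are learnable by the embedding models;
* evidence and frequency annotations with known per-filter survivor sets,
  recomputed inside the generator by direct predicates (never by the wrapper
  code they are meant to check).

Everything is driven by one seed; a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

NON_HUMAN_ORGANISMS = ("Bos taurus", "Saccharomyces cerevisiae", "Angelica gigas")


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic suite (defaults give roughly 500
    entities and 3,000 post-filter triples)."""

    n_compounds: int = 150
    n_targets: int = 80
    n_nonhuman_targets: int = 15
    n_genes: int = 60
    n_diseases: int = 40
    n_phenotypes: int = 60
    n_pathways: int = 15
    n_indications: int = 20
    n_side_effects: int = 30
    n_activities: int = 10
    n_effects: int = 12

    n_blocks: int = 4
    block_strength: float = 0.9
    hub_density: float = 1.0
    xref_noise: float = 0.0

    targets_per_drug: int = 6          # drug-source compound-target links
    targets_per_natural: int = 6       # natural-compound source links (mixed organisms)
    human_target_rate: float = 0.7
    indications_per_drug: int = 2
    side_effects_per_drug: int = 5
    genes_per_pgkb_compound: int = 4
    diseases_per_pgkb_compound: int = 2
    pgkb_gene_disease: int = 60
    phenos_per_disease: int = 14
    genes_per_hpo_disease: int = 2
    pathways_per_gene: int = 2
    interactions: int = 60
    activity_links_per_natural: int = 2
    effect_links_per_natural: int = 2
    atc_rate: float = 0.8
    reviewed_rate: float = 0.85
    frequency_present_rate: float = 0.7
    evidence_levels: tuple = (("1A", 0.15), ("1B", 0.10), ("2A", 0.15), ("2B", 0.15), ("3", 0.25), ("4", 0.20))
    hpo_evidence: tuple = (("TAS", 0.3), ("PCS", 0.2), ("IEA", 0.5))
    held_out_per_block: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("block_strength", "hub_density", "xref_noise", "human_target_rate",
                     "atc_rate", "reviewed_rate", "frequency_present_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows about its own output."""

    partition: dict[str, list[list[str]]]       # uid -> [(source, local_id), ...]
    kinds: dict[str, str]                       # uid -> NodeKind name
    blocks: dict[str, int]                      # uid -> latent block (blocked kinds)
    survivors: dict[str, dict]                  # per-filter raw/kept row keys
    expected_edges: list[list[str]] | None      # (uid, predicate, uid), dedup'd;
                                                # exact only at hub_density=1, noise=0
    held_out: list[list[str]]                   # unseen within-block (compound, target) uids
    counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _weighted(rng: np.random.Generator, pairs) -> str:
    labels = [p[0] for p in pairs]
    weights = np.array([p[1] for p in pairs], dtype=float)
    return labels[int(rng.choice(len(labels), p=weights / weights.sum()))]


def _pick(rng: np.random.Generator, pool: list, n: int, same_block: list, strength: float) -> list:
    """Choose up to n distinct items, preferring the same-block sub-pool."""
    n = min(n, len(pool))
    chosen: list = []
    same = [x for x in same_block if x in set(pool)]
    k_same = min(int(rng.binomial(n, strength)), len(same))
    if k_same:
        idx = rng.choice(len(same), size=k_same, replace=False)
        chosen.extend(same[i] for i in sorted(idx))
    rest = [x for x in pool if x not in set(chosen)]
    k_rest = min(n - len(chosen), len(rest))
    if k_rest:
        idx = rng.choice(len(rest), size=k_rest, replace=False)
        chosen.extend(rest[i] for i in sorted(idx))
    return chosen


class _Suite:
    """Internal builder holding the evolving ground truth."""

    def __init__(self, cfg: FixtureConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.partition: dict[str, list[list[str]]] = {}
        self.kinds: dict[str, str] = {}
        self.blocks: dict[str, int] = {}
        self.survivors: dict[str, dict] = {}
        self.edges: set[tuple[str, str, str]] = set()
        self.held_out: list[list[str]] = []
        self.counts: dict[str, int] = {}

    # -- identity bookkeeping ------------------------------------------

    def register(self, uid: str, kind: str, block: int | None = None) -> None:
        self.partition.setdefault(uid, [])
        self.kinds[uid] = kind
        if block is not None:
            self.blocks[uid] = block

    def mention(self, uid: str, source: str, local_id: str) -> None:
        self.partition[uid].append([source, local_id])

    def hub(self) -> bool:
        return bool(self.rng.random() < self.cfg.hub_density)

    def noise_xrefs(self) -> list[str]:
        if self.rng.random() < self.cfg.xref_noise:
            return [f"junkdb:J{int(self.rng.integers(0, 20)):03d}"]
        return []

    def edge(self, s_uid: str, pred: str, o_uid: str) -> None:
        self.edges.add((s_uid, pred, o_uid))


def generate_suite(cfg: FixtureConfig, outdir: str | Path) -> tuple[dict, GroundTruth]:
    """Write the nine-plus-one suite files and the ground-truth manifest.

    Returns ``(manifest, ground_truth)`` where the manifest maps source names
    to file paths (the phenotype source to its two files) and includes the
    two pivots.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    st = _Suite(cfg)
    rng = st.rng
    nb = cfg.n_blocks

    # ---- universes -----------------------------------------------------
    compounds = [f"COMPOUND#{i}" for i in range(cfg.n_compounds)]
    targets = [f"TARGET#{i}" for i in range(cfg.n_targets)]
    nh_targets = [f"TARGET#x{i}" for i in range(cfg.n_nonhuman_targets)]
    genes = [f"GENE#{i}" for i in range(cfg.n_genes)]
    diseases = [f"DISEASE#{i}" for i in range(cfg.n_diseases)]
    phenotypes = [f"PHENOTYPE#{i}" for i in range(cfg.n_phenotypes)]
    pathways = [f"PATHWAY#{i}" for i in range(cfg.n_pathways)]
    indications = [f"INDICATION#{i}" for i in range(cfg.n_indications)]
    side_effects = [f"SIDE_EFFECT#{i}" for i in range(cfg.n_side_effects)]
    activities = [f"ACTIVITY#{i}" for i in range(cfg.n_activities)]
    effects = [f"EFFECT#{i}" for i in range(cfg.n_effects)]

    for i, uid in enumerate(compounds):
        st.register(uid, "COMPOUND", i % nb)
    for i, uid in enumerate(targets):
        st.register(uid, "TARGET", i % nb)
    for uid in nh_targets:
        st.register(uid, "TARGET")
    for i, uid in enumerate(genes):
        st.register(uid, "GENE", i % nb)
    for i, uid in enumerate(diseases):
        st.register(uid, "DISEASE", i % nb)
    for i, uid in enumerate(phenotypes):
        st.register(uid, "PHENOTYPE", i % nb)
    for i, uid in enumerate(pathways):
        st.register(uid, "PATHWAY", i % nb)
    for i, uid in enumerate(indications):
        st.register(uid, "INDICATION", i % nb)
    for i, uid in enumerate(side_effects):
        st.register(uid, "SIDE_EFFECT", i % nb)
    for uid in activities + effects:
        st.register(uid, st_kind(uid))

    def block_of(uid: str) -> int:
        return st.blocks.get(uid, -1)

    def by_block(pool: list[str], b: int) -> list[str]:
        return [u for u in pool if st.blocks.get(u) == b]

    # hub cross-references
    cas = {uid: f"cas:50-{i:04d}-1" for i, uid in enumerate(compounds)}
    upacc = {uid: f"uniprot:P{i:05d}" for i, uid in enumerate(targets)}
    hgnc = {uid: f"hgnc:HGNC:{1000 + i}" for i, uid in enumerate(genes)}
    cui = {uid: f"C9{i:05d}" for i, uid in enumerate(diseases)}
    hp_term = {uid: f"HP:{i + 1:07d}" for i, uid in enumerate(phenotypes)}
    se_cui = {uid: f"umls:C8{i:05d}" for i, uid in enumerate(side_effects)}
    ind_cui = {uid: f"umls:C7{i:05d}" for i, uid in enumerate(indications)}

    # ATC leaf codes, unique per coded compound; ~8 leaves share each parent
    # chain so the classification levels are genuinely hierarchical
    atc_leaf: dict[str, str] = {}
    for i, uid in enumerate(compounds):
        if rng.random() < cfg.atc_rate:
            p, q = i // 8, i % 8
            atc_leaf[uid] = f"{'ANCJ'[p % 4]}{p:02d}AA{q:02d}"

    # source membership (overlapping subsets create the fusion problem)
    db_compounds = compounds[: int(cfg.n_compounds * 0.8)]
    sider_compounds = compounds[: int(cfg.n_compounds * 0.4)]
    pgkb_compounds = compounds[int(cfg.n_compounds * 0.2): int(cfg.n_compounds * 0.6)]
    npass_compounds = compounds[int(cfg.n_compounds * 0.6):]
    db_targets = targets[: int(cfg.n_targets * 0.65)]
    npass_targets = targets[int(cfg.n_targets * 0.35):]
    up_targets = targets[: int(cfg.n_targets * 0.9)]
    pgkb_genes = genes[: int(cfg.n_genes * 0.7)]
    hpo_genes = genes[int(cfg.n_genes * 0.3):]
    pgkb_diseases = diseases[: int(cfg.n_diseases * 0.6)]

    # ---- drug source (XML) ---------------------------------------------
    db_cid = {uid: f"DB{i:05d}" for i, uid in enumerate(db_compounds)}
    db_tid = {uid: f"BE{i:04d}" for i, uid in enumerate(db_targets)}
    interactions: dict[str, list[tuple[str, str]]] = {}
    for _ in range(cfg.interactions):
        a, b = (db_compounds[int(i)] for i in rng.choice(len(db_compounds), 2, replace=False))
        itype = "increases_efficacy" if rng.random() < 0.5 else "decreases_efficacy"
        interactions.setdefault(a, []).append((db_cid[b], itype))
        st.edge(a, itype, b)
    emitted_targets: set[str] = set()
    lines = ["<drugbank version=\"1\">"]
    for uid in db_compounds:
        st.mention(uid, "drugbank", db_cid[uid])
        lines.append(f'  <drug id="{db_cid[uid]}">')
        lines.append(f"    <name>compound {uid.split('#')[1]}</name>")
        xr = ([cas[uid]] if st.hub() else []) + st.noise_xrefs()
        for chunk in xr:
            ns, _, ident = chunk.partition(":")
            lines.append(f'    <xref ns="{ns}" id="{ident}"/>')
        if uid in atc_leaf:
            code = atc_leaf[uid]
            lines.append(f'    <atc code="{code}">')
            for plen in (5, 4, 3, 1):
                lines.append(f'      <parent code="{code[:plen]}"/>')
            lines.append("    </atc>")
            st.edge(uid, "has_code", code)
            chain = [code, code[:5], code[:4], code[:3], code[:1]]
            for child, parent in zip(chain, chain[1:]):
                st.edge(child, "subclass_of", parent)
        picked = _pick(rng, db_targets, cfg.targets_per_drug,
                       by_block(db_targets, block_of(uid)), cfg.block_strength)
        for t_uid in picked:
            tid = db_tid[t_uid]
            if t_uid not in emitted_targets:
                emitted_targets.add(t_uid)
                st.mention(t_uid, "drugbank", tid)
                txr = ([upacc[t_uid]] if st.hub() else []) + st.noise_xrefs()
            else:
                txr = []
            xr_tags = "".join(
                f'<xref ns="{c.partition(":")[0]}" id="{c.partition(":")[2]}"/>' for c in txr
            )
            lines.append(
                f'    <target id="{tid}" organism="Homo sapiens">'
                f"<name>target {t_uid.split('#')[1]}</name>{xr_tags}</target>"
            )
            st.edge(uid, "has_target", t_uid)
        for other_lid, itype in interactions.get(uid, []):
            lines.append(f'    <interaction drug="{other_lid}" type="{itype}"/>')
        lines.append("  </drug>")
    lines.append("</drugbank>")
    (outdir / "drugbank.xml").write_text("\n".join(lines) + "\n", encoding="utf-8")

    # ---- side-effect source (TSV) ---------------------------------------
    sd_cid = {uid: f"CID{i:06d}" for i, uid in enumerate(sider_compounds)}
    rows = []
    for i, uid in enumerate(indications):
        rows.append(f"indication\tSI{i:04d}\tindication {i}\t{ind_cui[uid]}")
        st.mention(uid, "sider", f"SI{i:04d}")
    for i, uid in enumerate(side_effects):
        rows.append(f"side_effect\tSE{i:04d}\tside effect {i}\t{se_cui[uid]}")
        st.mention(uid, "sider", f"SE{i:04d}")
    ind_lid = {uid: f"SI{i:04d}" for i, uid in enumerate(indications)}
    se_lid = {uid: f"SE{i:04d}" for i, uid in enumerate(side_effects)}
    for uid in sider_compounds:
        st.mention(uid, "sider", sd_cid[uid])
        xr = ([cas[uid]] if st.hub() else []) + st.noise_xrefs()
        rows.append(f"drug\t{sd_cid[uid]}\tcompound {uid.split('#')[1]}\t{';'.join(xr)}")
        b = block_of(uid)
        for o in _pick(rng, indications, cfg.indications_per_drug, by_block(indications, b), cfg.block_strength):
            rows.append(f"link\t{sd_cid[uid]}\thas_indication\t{ind_lid[o]}")
            st.edge(uid, "has_indication", o)
        for o in _pick(rng, side_effects, cfg.side_effects_per_drug, by_block(side_effects, b), cfg.block_strength):
            rows.append(f"link\t{sd_cid[uid]}\thas_side_effect\t{se_lid[o]}")
            st.edge(uid, "has_side_effect", o)
    (outdir / "sider.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    # ---- pharmacogenomic source (TSV) -----------------------------------
    pg_cid = {uid: f"PA{i + 100}" for i, uid in enumerate(pgkb_compounds)}
    pg_gid = {uid: f"PAG{i + 100}" for i, uid in enumerate(pgkb_genes)}
    pg_did = {uid: f"PAD{i + 100}" for i, uid in enumerate(pgkb_diseases)}
    rows = []
    atc_raw: list[str] = []
    for uid in pgkb_compounds:
        st.mention(uid, "pharmgkb", pg_cid[uid])
        xr = ([cas[uid]] if st.hub() else []) + st.noise_xrefs()
        codes = []
        if uid in atc_leaf:
            codes = [atc_leaf[uid], atc_leaf[uid][:3]]   # substance + class code
        atc_raw.extend(codes)
        xr += [f"atc:{c}" for c in codes]
        rows.append(f"compound\t{pg_cid[uid]}\tcompound {uid.split('#')[1]}\t{';'.join(xr)}")
    for uid in pgkb_genes:
        st.mention(uid, "pharmgkb", pg_gid[uid])
        xr = ([hgnc[uid]] if st.hub() else []) + st.noise_xrefs()
        rows.append(f"gene\t{pg_gid[uid]}\tgene {uid.split('#')[1]}\t{';'.join(xr)}")
    for uid in pgkb_diseases:
        st.mention(uid, "pharmgkb", pg_did[uid])
        xr = ([f"umls:{cui[uid]}"] if st.hub() else []) + st.noise_xrefs()
        rows.append(f"disease\t{pg_did[uid]}\tdisease {uid.split('#')[1]}\t{';'.join(xr)}")
    ann_raw: list[dict] = []

    def pg_ann(s_lid: str, pred: str, o_lid: str, s_uid: str, o_uid: str) -> None:
        level = _weighted(rng, cfg.evidence_levels)
        rows.append(f"ann\t{s_lid}\t{pred}\t{o_lid}\t{level}")
        kept = level in {"1A", "1B", "2A", "2B"}
        ann_raw.append({"subject": s_lid, "predicate": pred, "object": o_lid,
                        "evidence": level, "kept": kept})
        if kept:
            st.edge(s_uid, pred, o_uid)

    for uid in pgkb_compounds:
        b = block_of(uid)
        for g in _pick(rng, pgkb_genes, cfg.genes_per_pgkb_compound, by_block(pgkb_genes, b), cfg.block_strength):
            pg_ann(pg_cid[uid], "is_affecting", pg_gid[g], uid, g)
        for d in _pick(rng, pgkb_diseases, cfg.diseases_per_pgkb_compound, by_block(pgkb_diseases, b), cfg.block_strength):
            pg_ann(pg_cid[uid], "is_substance_that_treats", pg_did[d], uid, d)
    for _ in range(cfg.pgkb_gene_disease):
        g = pgkb_genes[int(rng.integers(0, len(pgkb_genes)))]
        d_pool = by_block(pgkb_diseases, block_of(g)) or pgkb_diseases
        d = d_pool[int(rng.integers(0, len(d_pool)))]
        pg_ann(pg_gid[g], "causes_condition", pg_did[d], g, d)
    (outdir / "pharmgkb.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    st.survivors["pharmgkb_evidence"] = {
        "raw": len(ann_raw),
        "kept_rows": sorted(
            [r["subject"], r["predicate"], r["object"]] for r in ann_raw if r["kept"]
        ),
    }
    st.survivors["atc_codes"] = {
        "raw": sorted(atc_raw),
        "kept": sorted(c for c in atc_raw if len(c) == 7),
    }

    # ---- natural-compound source (TSV) -----------------------------------
    np_cid = {uid: f"NPC{i + 1000}" for i, uid in enumerate(npass_compounds)}
    np_tid = {uid: f"NPT{i + 1000}" for i, uid in enumerate(npass_targets)}
    np_tid.update({uid: f"NPX{i}" for i, uid in enumerate(nh_targets)})
    nh_org = {uid: NON_HUMAN_ORGANISMS[i % len(NON_HUMAN_ORGANISMS)]
              for i, uid in enumerate(nh_targets)}
    rows = []
    for i, uid in enumerate(activities):
        rows.append(f"activity\tNPA{i}\tactivity {i}")
        st.mention(uid, "npass", f"NPA{i}")
    for i, uid in enumerate(effects):
        rows.append(f"effect\tNPE{i}\teffect {i}")
        st.mention(uid, "npass", f"NPE{i}")
    for uid in npass_targets:
        st.mention(uid, "npass", np_tid[uid])
        xr = ([upacc[uid]] if st.hub() else []) + st.noise_xrefs()
        rows.append(f"target\t{np_tid[uid]}\ttarget {uid.split('#')[1]}\t{';'.join(xr)}\tHomo sapiens")
    for uid in nh_targets:
        st.mention(uid, "npass", np_tid[uid])
        rows.append(f"target\t{np_tid[uid]}\tnon-human target {uid.split('#')[1]}\t\t{nh_org[uid]}")
    ht_raw: list[dict] = []
    act_lid = {uid: f"NPA{i}" for i, uid in enumerate(activities)}
    eff_lid = {uid: f"NPE{i}" for i, uid in enumerate(effects)}
    for uid in npass_compounds:
        st.mention(uid, "npass", np_cid[uid])
        xr = ([cas[uid]] if st.hub() else []) + st.noise_xrefs()
        rows.append(f"compound\t{np_cid[uid]}\tcompound {uid.split('#')[1]}\t{';'.join(xr)}")
        b = block_of(uid)
        n_human = int(rng.binomial(cfg.targets_per_natural, cfg.human_target_rate))
        picked_h = _pick(rng, npass_targets, n_human, by_block(npass_targets, b), cfg.block_strength)
        picked_nh = _pick(rng, nh_targets, cfg.targets_per_natural - n_human, [], 0.0)
        for t_uid in picked_h + picked_nh:
            organism = "Homo sapiens" if t_uid in set(picked_h) else nh_org[t_uid]
            rows.append(f"link\t{np_cid[uid]}\thas_target\t{np_tid[t_uid]}\t{organism}")
            kept = organism == "Homo sapiens"
            ht_raw.append({"subject": np_cid[uid], "object": np_tid[t_uid],
                           "organism": organism, "kept": kept})
            if kept:
                st.edge(uid, "has_target", t_uid)
        for a_uid in _pick(rng, activities, cfg.activity_links_per_natural, [], 0.0):
            pred = ("has_activity", "increases_activity", "decreases_activity")[int(rng.integers(0, 3))]
            rows.append(f"link\t{np_cid[uid]}\t{pred}\t{act_lid[a_uid]}")
            st.edge(uid, pred, a_uid)
        for e_uid in _pick(rng, effects, cfg.effect_links_per_natural, [], 0.0):
            pred = ("has_effect", "increases_effect", "decreases_effect")[int(rng.integers(0, 3))]
            rows.append(f"link\t{np_cid[uid]}\t{pred}\t{eff_lid[e_uid]}")
            st.edge(uid, pred, e_uid)
    (outdir / "npass.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    st.survivors["npass_human"] = {
        "raw": len(ht_raw),
        "kept_rows": sorted([r["subject"], r["object"]] for r in ht_raw if r["kept"]),
    }

    # ---- phenotype source: ontology (OBO) + annotations (TSV) ------------
    obo = ["format-version: 1.2", "ontology: synthetic-phenotypes", ""]
    for i, uid in enumerate(phenotypes):
        st.mention(uid, "hpo", hp_term[uid])
        obo += [f"[Term]", f"id: {hp_term[uid]}", f"name: phenotype {i}"]
        if i > 0 and i % 5:
            obo.append(f"is_a: {hp_term[phenotypes[i - (i % 5)]]} ! parent")
        obo.append(f"xref: UMLS:C6{i:05d}")
        obo.append("")
    (outdir / "hpo_ontology.obo").write_text("\n".join(obo) + "\n", encoding="utf-8")

    hd_lid = {uid: f"HD{i + 1:05d}" for i, uid in enumerate(diseases)}
    hg_lid = {uid: f"HG{i}" for i, uid in enumerate(hpo_genes)}
    rows = []
    for uid in diseases:
        st.mention(uid, "hpo", hd_lid[uid])
        rows.append(f"disease\t{hd_lid[uid]}\tdisease {uid.split('#')[1]}\t")
    for uid in hpo_genes:
        st.mention(uid, "hpo", hg_lid[uid])
        xr = ([hgnc[uid]] if st.hub() else []) + st.noise_xrefs()
        rows.append(f"gene\t{hg_lid[uid]}\tgene {uid.split('#')[1]}\t{';'.join(xr)}")
    pheno_raw: list[dict] = []
    for uid in diseases:
        b = block_of(uid)
        for p_uid in _pick(rng, phenotypes, cfg.phenos_per_disease, by_block(phenotypes, b), cfg.block_strength):
            freq_text, frac = "", None
            evidence = ""
            if rng.random() < cfg.frequency_present_rate:
                form = int(rng.integers(0, 3))
                if form == 0:
                    den = int(rng.integers(4, 21))
                    num = int(rng.integers(0, den + 1))
                    freq_text, frac = f"{num}/{den}", num / den
                elif form == 1:
                    pct = int(rng.integers(0, 101))
                    freq_text, frac = f"{pct}%", pct / 100.0
                else:
                    band, lower = (
                        ("Excluded", 0.0), ("Very rare", 0.01), ("Occasional", 0.05),
                        ("Frequent", 0.30), ("Very frequent", 0.80), ("Obligate", 1.0),
                    )[int(rng.integers(0, 6))]
                    freq_text, frac = band, lower
                evidence = _weighted(rng, cfg.hpo_evidence) if rng.random() < 0.5 else ""
            else:
                evidence = _weighted(rng, cfg.hpo_evidence)
            rows.append(f"pheno_ann\t{hd_lid[uid]}\t{hp_term[p_uid]}\t{freq_text}\t{evidence}")
            kept = frac >= 0.30 if frac is not None else evidence in {"TAS", "PCS"}
            pheno_raw.append({"subject": hd_lid[uid], "object": hp_term[p_uid],
                              "frequency": freq_text, "evidence": evidence, "kept": kept})
            if kept:
                st.edge(uid, "has_phenotype", p_uid)
    for uid in diseases:
        pool = by_block(hpo_genes, block_of(uid)) or hpo_genes
        for g_uid in _pick(rng, pool, cfg.genes_per_hpo_disease, [], 0.0):
            rows.append(f"gene_ann\t{hg_lid[g_uid]}\t{hd_lid[uid]}")
            st.edge(g_uid, "causes_condition", uid)
    (outdir / "hpo_annotations.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    st.survivors["hpo_frequency"] = {
        "raw": len(pheno_raw),
        "kept_rows": sorted([r["subject"], r["object"]] for r in pheno_raw if r["kept"]),
    }

    # ---- pivots ----------------------------------------------------------
    omim_code = {uid: f"{600000 + i}" for i, uid in enumerate(diseases)}
    pivot = []
    hpo_linked: set[str] = set()
    for uid in diseases:
        concept = cui[uid]
        if st.hub():
            pivot.append(f"{concept}\thpo_disease\t{hd_lid[uid]}")
            hpo_linked.add(uid)
        pivot.append(f"{concept}\tomim\t{omim_code[uid]}")
    # decoy concepts: OMIM codes unreachable from any integrated disease
    decoys = [f"CX{i:05d}" for i in range(10)]
    for i, concept in enumerate(decoys):
        pivot.append(f"{concept}\tomim\t{700000 + i}")
    (outdir / "umls_pivot.tsv").write_text("\n".join(pivot) + "\n", encoding="utf-8")
    st.survivors["omim_via_umls"] = {
        "all_omim": sorted([omim_code[u] for u in diseases] + [str(700000 + i) for i in range(10)]),
        "kept": sorted(omim_code[u] for u in sorted(hpo_linked)),
    }
    orpha = []
    for i, uid in enumerate(diseases):
        if i % 2 == 0:
            orpha.append(f"ORPHA:{i + 1}\thpo_disease\t{hd_lid[uid]}")
    (outdir / "orphanet_pivot.tsv").write_text("\n".join(orpha) + "\n", encoding="utf-8")

    # ---- pathway source (TSV) --------------------------------------------
    rw_gid = {uid: f"RG{i}" for i, uid in enumerate(genes)}
    rw_pid = {uid: f"R-HSA-{i + 100}" for i, uid in enumerate(pathways)}
    rows = []
    for uid in pathways:
        st.mention(uid, "reactome", rw_pid[uid])
        rows.append(f"pathway\t{rw_pid[uid]}\tpathway {uid.split('#')[1]}\treactome:{rw_pid[uid]}")
    for uid in genes:
        st.mention(uid, "reactome", rw_gid[uid])
        xr = ([hgnc[uid]] if st.hub() else []) + st.noise_xrefs()
        rows.append(f"gene\t{rw_gid[uid]}\tgene {uid.split('#')[1]}\t{';'.join(xr)}")
        b = block_of(uid)
        for p_uid in _pick(rng, pathways, cfg.pathways_per_gene, by_block(pathways, b), cfg.block_strength):
            rows.append(f"link\t{rw_gid[uid]}\tacts_within\t{rw_pid[p_uid]}")
            st.edge(uid, "acts_within", p_uid)
    (outdir / "reactome.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    # ---- protein source (XML) --------------------------------------------
    lines = ["<uniprot version=\"1\">"]
    up_raw: list[dict] = []
    for uid in up_targets:
        acc = upacc[uid].split(":", 1)[1]
        reviewed = bool(rng.random() < cfg.reviewed_rate)
        dataset = "Swiss-Prot" if reviewed else "TrEMBL"
        if reviewed:
            # unreviewed entries never pass the wrapper filter, so they are
            # not part of the planted identity partition
            st.mention(uid, "uniprot", acc)
        g_pool = by_block(genes, block_of(uid)) or genes
        g_uid = g_pool[int(rng.integers(0, len(g_pool)))]
        g_ns, g_id = hgnc[g_uid].split(":", 1)
        lines.append(
            f'  <entry id="{acc}" dataset="{dataset}">'
            f"<name>target {uid.split('#')[1]}</name>"
            f"<organism>Homo sapiens</organism>"
            f'<gene ns="{g_ns}" id="{g_id}"/></entry>'
        )
        # endpoints known iff the protein and the gene were integrated upstream
        protein_known = uid in set(db_targets) or uid in set(npass_targets)
        kept = reviewed and protein_known
        up_raw.append({"accession": acc, "gene": g_id, "reviewed": reviewed, "kept": kept})
        if kept:
            st.edge(uid, "gene_product_of", g_uid)
    lines.append("</uniprot>")
    (outdir / "uniprot.xml").write_text("\n".join(lines) + "\n", encoding="utf-8")
    st.survivors["uniprot_known"] = {
        "raw": len(up_raw),
        "kept_rows": sorted([r["accession"], r["gene"]] for r in up_raw if r["kept"]),
    }

    # ---- held-out within-block compound-target pairs ---------------------
    linked = {(s, o) for s, p, o in st.edges if p == "has_target"}
    for b in range(nb):
        pool_c = by_block(db_compounds, b)
        pool_t = [t for t in by_block(db_targets, b) if t in emitted_targets]
        found = 0
        for c_uid in pool_c:
            for t_uid in pool_t:
                if found >= cfg.held_out_per_block:
                    break
                if (c_uid, t_uid) not in linked:
                    st.held_out.append([c_uid, t_uid])
                    found += 1
            if found >= cfg.held_out_per_block:
                break

    # ---- manifest --------------------------------------------------------
    exact = cfg.hub_density == 1.0 and cfg.xref_noise == 0.0
    expected_edges = sorted(list(e) for e in st.edges) if exact else None
    st.counts = {
        "entities": len(st.partition) + len({c for chain in
                       ([atc_leaf[u], atc_leaf[u][:5], atc_leaf[u][:4], atc_leaf[u][:3], atc_leaf[u][:1]]
                        for u in atc_leaf) for c in chain}),
        "planted_edges": len(st.edges),
        "mentions": sum(len(v) for v in st.partition.values()),
    }
    gt = GroundTruth(
        partition={k: v for k, v in st.partition.items() if v},
        kinds=st.kinds,
        blocks=st.blocks,
        survivors=st.survivors,
        expected_edges=expected_edges,
        held_out=st.held_out,
        counts=st.counts,
    )
    (outdir / "ground_truth.json").write_text(gt.to_json(), encoding="utf-8")
    manifest = {
        "drugbank": str(outdir / "drugbank.xml"),
        "sider": str(outdir / "sider.tsv"),
        "pharmgkb": str(outdir / "pharmgkb.tsv"),
        "npass": str(outdir / "npass.tsv"),
        "hpo": {
            "annotations": str(outdir / "hpo_annotations.tsv"),
            "ontology": str(outdir / "hpo_ontology.obo"),
        },
        "reactome": str(outdir / "reactome.tsv"),
        "uniprot": str(outdir / "uniprot.xml"),
        "umls": str(outdir / "umls_pivot.tsv"),
        "orphanet": str(outdir / "orphanet_pivot.tsv"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest, gt


def st_kind(uid: str) -> str:
    return uid.split("#", 1)[0]


def load_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(**data)
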