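"""Packaged composition profiles, marker panels and annotation signatures.

The study design has three conditions — healthy lung, LLC1 (orthotopic Lewis
lung carcinoma) and Kras-driven (Kras LA2) lung adenocarcinoma — with sorted
CD45+ cells falling into four major immune compartments (B, T, NK,
macrophage) that subdivide into 20 transcriptional subtypes.  The fractions
below are the compartment and subset percentages reported for each condition;
they serve simultaneously as generator ground truth and as recovery targets
for the clustering/annotation pipeline.

Marker panels are canonical mouse immune genes.  They play two roles: the
synthetic generator boosts them in the owning population, and the annotation
step scores clusters against them as signatures.  Condition panels mimic the
condition-specific transcriptional programs (stress/activation genes induced
per compartment per condition).
"""

from __future__ import annotations

from .synthetic import CompositionProfile, ProgramSpec

CONDITIONS = ("healthy", "LLC1", "Kras")
COMPARTMENTS = ("B", "T", "NK", "macrophage")

# Major-compartment percentages of CD45+ cells per condition.
COMPARTMENT_PERCENT = {
    "healthy": {"B": 36.8, "T": 39.4, "NK": 10.1, "macrophage": 13.7},
    "LLC1": {"B": 62.7, "T": 20.2, "NK": 6.5, "macrophage": 10.6},
    "Kras": {"B": 39.2, "T": 40.8, "NK": 9.3, "macrophage": 10.7},
}

# Subset percentages within each compartment per condition.  Plasma cells are
# the remainder to 100% of the B compartment (reported only as "<1%").
SUBSET_PERCENT = {
    "B": {
        "healthy": {"mature_B": 11.5, "resting_B": 66.4, "pre_Bcr": 10.6,
                    "late_proB": 10.5, "plasma_cell": 1.0},
        "LLC1": {"mature_B": 8.1, "resting_B": 76.5, "pre_Bcr": 12.2,
                 "late_proB": 2.8, "plasma_cell": 0.4},
        "Kras": {"mature_B": 81.5, "resting_B": 5.0, "pre_Bcr": 3.9,
                 "late_proB": 9.0, "plasma_cell": 0.6},
    },
    "T": {
        "healthy": {"Cd4_T": 42.6, "Cd8_T": 28.2, "Cd8_memory_T": 9.4,
                    "activated_Cd8_T": 5.9, "Treg": 10.2, "Th17": 3.7},
        "LLC1": {"Cd4_T": 32.2, "Cd8_T": 25.5, "Cd8_memory_T": 16.8,
                 "activated_Cd8_T": 6.7, "Treg": 15.5, "Th17": 3.3},
        "Kras": {"Cd4_T": 30.2, "Cd8_T": 25.2, "Cd8_memory_T": 14.0,
                 "activated_Cd8_T": 13.9, "Treg": 12.9, "Th17": 3.8},
    },
    "NK": {
        "healthy": {"Fcgr3_high_NK": 53.7, "Fcgr3_low_NK": 40.3, "Xcl1_NK": 6.0},
        "LLC1": {"Fcgr3_high_NK": 55.7, "Fcgr3_low_NK": 36.1, "Xcl1_NK": 6.0},
        "Kras": {"Fcgr3_high_NK": 49.2, "Fcgr3_low_NK": 45.0, "Xcl1_NK": 5.8},
    },
    "macrophage": {
        "healthy": {"Ccr2_mac": 47.8, "Ace_mac": 21.3, "Cd3_mac": 13.2,
                    "Bcr_mac": 8.8, "MHCII_mac": 7.4, "metabolic_mac": 0.6},
        "LLC1": {"Ccr2_mac": 32.8, "Ace_mac": 27.0, "Cd3_mac": 11.1,
                 "Bcr_mac": 13.6, "MHCII_mac": 11.4, "metabolic_mac": 3.98},
        "Kras": {"Ccr2_mac": 36.8, "Ace_mac": 19.7, "Cd3_mac": 15.4,
                 "Bcr_mac": 14.7, "MHCII_mac": 12.8, "metabolic_mac": 0.6},
    },
}

SUBTYPE_COMPARTMENT = {
    subtype: compartment
    for compartment, by_cond in SUBSET_PERCENT.items()
    for subtype in by_cond["healthy"]
}

# Identity markers: boosted in every cell of the compartment / subtype,
# regardless of condition; doubles as the annotation signature.
COMPARTMENT_MARKERS = {
    "B": ["Cd19", "Ms4a1", "Cd79a", "Cd79b", "Ebf1", "Pax5", "Ighm", "Iglc1"],
    "T": ["Cd3e", "Cd3d", "Cd3g", "Trac", "Trbc1", "Lat", "Thy1", "Cd28"],
    "NK": ["Ncr1", "Klrb1c", "Klre1", "Gzma", "Prf1", "Eomes", "Nkg7", "Klrk1"],
    "macrophage": ["Adgre1", "Csf1r", "Lyz2", "Fcgr1", "Mertk", "Itgam",
                   "Cd68", "Mafb"],
}

SUBTYPE_MARKERS = {
    "mature_B": ["Ighd", "Cd83", "Cr2", "Fcer2a", "Cd22", "Cd37", "H2-Ob",
                 "Ltb", "Parm1", "Ralgps2", "Fchsd2", "Swap70"],
    "resting_B": ["Fcrl1", "Cd55", "Bank1", "Siglecg", "Fcmr", "Btla",
                  "Cd72", "Blk", "Blnk", "Hvcn1", "Tspan32", "Gng7"],
    "plasma_cell": ["Jchain", "Xbp1", "Prdm1", "Sdc1", "Irf4", "Derl3",
                    "Slamf7", "Tnfrsf17", "Eaf2", "Mzb1", "Edem1", "Sec11c"],
    "pre_Bcr": ["Vpreb1", "Igll1", "Dntt", "Rag1", "Vpreb3", "Cd24a", "Myb",
                "Akap12", "Ssbp2", "Smad1", "Plcl2", "Tifa"],
    "late_proB": ["Rag2", "Kit", "Flt3", "Sox4", "Mki67", "Top2a", "Tuba1b",
                  "Stmn1", "Birc5", "Cdk1", "Lig1", "Tyms"],
    "Cd4_T": ["Cd4", "Cd40lg", "Icos", "Lef1", "Tnfsf8", "Cd5", "Itk",
              "Rasgrp1", "Tespa1", "Foxp1", "Satb1", "Cd6"],
    "Cd8_T": ["Cd8a", "Cd8b1", "Dapl1", "S1pr1", "Klf3", "Txk", "Itgae",
              "Gimap3", "Gimap4", "Art2b", "Cd247", "Themis"],
    "Cd8_memory_T": ["Il7r", "Sell", "Tcf7", "Bcl2", "Slamf6", "Id3",
                     "Bach2", "Dusp10", "Klrg1", "Traf5", "Cd44", "Cmah"],
    "activated_Cd8_T": ["Gzmb", "Ifng", "Pdcd1", "Zeb2", "Gzmk", "Lag3",
                        "Havcr2", "Tigit", "Tox", "Ctsw", "Serpinb9", "Chst12"],
    "Th17": ["Rorc", "Il17a", "Il17f", "Ccr6", "Il23r", "Il1r1", "Ahr",
             "Maf", "Ccr4", "Il22", "Tmem176a", "Tmem176b"],
    "Treg": ["Foxp3", "Il2ra", "Ctla4", "Ikzf2", "Tnfrsf18", "Tnfrsf4",
             "Nrp1", "Capg", "Ikzf4", "Itgb8", "Socs2", "Ptger2"],
    "Fcgr3_high_NK": ["Fcgr3", "Klra4", "Spn", "Itga2", "Klra8", "Klrb1b",
                      "Cx3cr1", "S1pr5", "Adgrg1", "Lair1", "Gzmc", "Prdm16"],
    "Fcgr3_low_NK": ["Emb", "Cd27", "Tnfsf10", "Cxcr3", "Itga1", "Cd96",
                     "Klri2", "Sh2d1b1", "Tnfrsf9", "Ctla2a", "Ildr1", "Inpp4b"],
    "Xcl1_NK": ["Xcl1", "Cd160", "Klrc2", "Socs3", "Capn3", "Batf3", "Cd7",
                "Ltb4r1", "Smpdl3b", "Ramp1", "Ncald", "Tmem37"],
    "Ccr2_mac": ["Ccr2", "Ly6c1", "Nr4a1", "F13a1", "Ms4a4c", "Ccr1",
                 "Vcan", "Fn1", "Chil3", "Plac8", "S100a4", "Ifitm3"],
    "Ace_mac": ["Ace", "Treml4", "Ear2", "Eno3", "Cd300e", "Fcgr4",
                "Ceacam1", "Cebpb", "Itgal", "Slc12a2", "Pglyrp1", "Spic"],
    "Bcr_mac": ["Bcr", "Gngt2", "Ifitm6", "Ms4a7", "Cd300a", "Fcrls",
                "Tmem119", "Hexb", "Olfml3", "Sparc", "Siglech", "Ctss"],
    "Cd3_mac": ["Cd5l", "Vsig4", "Clec4f", "Timd4", "Marco", "Cd163",
                "Folr2", "Lyve1", "Mrc1", "Gas6", "Selenop", "Stab1"],
    "metabolic_mac": ["Ldha", "Slc2a1", "Hk2", "Vegfa", "Pgk1", "Pgam1",
                      "Aldoa", "Tpi1", "Pfkl", "Eno1", "Pdk1", "Egln3"],
    "MHCII_mac": ["H2-Ab1", "H2-Aa", "Cd74", "Ciita", "H2-Eb1", "H2-DMa",
                  "H2-DMb1", "Tapbp", "Cd209a", "Itgax", "Napsa", "Flt3l"],
}

# Condition programs: induced in a whole compartment under one condition,
# mirroring the reported condition-specific gene programs (e.g. immediate-early
# stress genes in LLC1 B cells).
CONDITION_MARKERS = {
    ("B", "healthy"): ["Zfp36l2", "Ccr7", "Btg2"],
    ("B", "LLC1"): ["Ier5", "Jun", "Fos"],
    ("B", "Kras"): ["Fau", "Ubb", "Serf2"],
    ("T", "healthy"): ["Crlf3", "Lck", "Saraf"],
    ("T", "LLC1"): ["Ier2", "Stk17b", "Ifngr1"],
    ("T", "Kras"): ["Grip2", "Gm10269", "Uba52"],
    ("NK", "healthy"): ["Lgals1", "S100a10", "Anxa2"],
    ("NK", "LLC1"): ["Dusp2", "Klf6", "Ubc"],
    ("NK", "Kras"): ["Klrc1", "Psme2b", "Ly6c2"],
    ("macrophage", "healthy"): ["Hspa1a", "Hspa1b", "Gpr141"],
    ("macrophage", "LLC1"): ["Pim1", "S100a11", "Neat1"],
    ("macrophage", "Kras"): ["Ccl5", "Cox7c", "Krt80"],
}

COMPARTMENT_BOOST = 2.0  # natural-log mean shift for identity markers
SUBTYPE_BOOST = 2.0
CONDITION_BOOST = 1.2


def _check_marker_uniqueness() -> None:
    seen: dict[str, str] = {}
    panels = (
        [(f"compartment:{c}", genes) for c, genes in COMPARTMENT_MARKERS.items()]
        + [(f"subtype:{s}", genes) for s, genes in SUBTYPE_MARKERS.items()]
        + [(f"condition:{k}", genes) for k, genes in CONDITION_MARKERS.items()]
    )
    for owner, genes in panels:
        for g in genes:
            if g in seen:
                raise ValueError(f"marker gene {g} assigned to both {seen[g]} and {owner}")
            seen[g] = owner


_check_marker_uniqueness()


def _normalized(fracs: dict[str, float]) -> dict[str, float]:
    total = sum(fracs.values())
    return {k: v / total for k, v in fracs.items()}


def full_profile(condition: str) -> CompositionProfile:
    """All-compartment composition over the 20 subtypes for one condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    comp = _normalized(COMPARTMENT_PERCENT[condition])
    fracs: dict[str, float] = {}
    for compartment, p_comp in comp.items():
        sub = _normalized(SUBSET_PERCENT[compartment][condition])
        for subtype, p_sub in sub.items():
            fracs[subtype] = p_comp * p_sub
    return CompositionProfile(condition=condition, subtype_fractions=fracs,
                              compartment_of=dict(SUBTYPE_COMPARTMENT))


def compartment_profile(compartment: str, condition: str) -> CompositionProfile:
    """Composition restricted to one compartment's subtypes for one condition."""
    if compartment not in SUBSET_PERCENT:
        raise ValueError(f"unknown compartment {compartment!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    fracs = _normalized(SUBSET_PERCENT[compartment][condition])
    comp_of = {s: compartment for s in fracs}
    return CompositionProfile(condition=condition, subtype_fractions=fracs,
                              compartment_of=comp_of)


def default_programs(compartment: str | None = None) -> list[ProgramSpec]:
    """Marker programs for the generator.

    With ``compartment=None`` the full design: compartment identity markers,
    subtype identity markers, and per-condition compartment programs.  With a
    compartment given, only the programs relevant to its subtypes (identity
    compartment markers are still included so compartment-restricted data keep
    their lineage signature).
    """
    progs: list[ProgramSpec] = []
    compartments = COMPARTMENTS if compartment is None else (compartment,)
    for c in compartments:
        progs.append(ProgramSpec(subtype=c, condition=None,
                                 marker_genes=list(COMPARTMENT_MARKERS[c]),
                                 log_fold_boost=COMPARTMENT_BOOST))
        for (cc, cond), genes in CONDITION_MARKERS.items():
            if cc == c:
                progs.append(ProgramSpec(subtype=c, condition=cond,
                                         marker_genes=list(genes),
                                         log_fold_boost=CONDITION_BOOST))
    for subtype, comp in SUBTYPE_COMPARTMENT.items():
        if comp in compartments:
            progs.append(ProgramSpec(subtype=subtype, condition=None,
                                     marker_genes=list(SUBTYPE_MARKERS[subtype]),
                                     log_fold_boost=SUBTYPE_BOOST))
    return progs


def compartment_signatures() -> dict[str, list[str]]:
    """Signatures for annotating top-level clusters to major compartments."""
    return {c: list(g) for c, g in COMPARTMENT_MARKERS.items()}


def subtype_signatures(compartment: str) -> dict[str, list[str]]:
    """Signatures for annotating subclusters within one compartment."""
    return {s: list(SUBTYPE_MARKERS[s])
            for s, c in SUBTYPE_COMPARTMENT.items() if c == compartment}
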