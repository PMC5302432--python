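"""Published reference values for a Swedish organic winter-wheat trial.

Nineteen winter wheat genotypes (selections, old cultivars, primitive
wheats, spelts, landraces and modern cultivars) were grown organically at
one locality over three harvest years (2012-2014) with two replicates.
The tables below hold the published genotype-level results of that trial:
three-year mean grain yields (kg·ha⁻¹ at 13% moisture, already corrected
for dehulling in the hulled groups), three-year mean nutritional yields of
Fe, Zn, Cu and Mg (adults·ha⁻¹·year⁻¹), and, for six study genotypes plus
six externally reported conventional/intensive wheats, mean wholemeal
mineral concentrations (mg·kg⁻¹).

These values serve as inputs: the worked-example dataset in
:mod:`nutmet.simulate` is reverse-engineered from them, and the published
literature rows let nutritional yield and nutrient density be compared
across production systems.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "MINERALS",
    "genotype_means",
    "study_concentrations",
    "literature_rows",
]

#: Mineral panel of the reference trial, in reporting order.
MINERALS = ["Fe", "Zn", "Cu", "Mg"]

# (id, name, group, yield, NY_Fe, NY_Zn, NY_Cu, NY_Mg)
# Yield in kg/ha (dehulling-corrected for Spelt/Primitive); nutritional
# yields in adults/ha/year, three-year genotype means.
_GENOTYPE_MEANS = [
    (1, "5113", "Selection", 3807, 39, 47, 65, 47),
    (4, "Borstvete Gotland", "Landrace", 3619, 36, 46, 71, 45),
    (9, "Jacoby", "Landrace", 4595, 40, 51, 70, 50),
    (17, "Ure", "Cultivar", 4470, 37, 42, 57, 48),
    (10, "Oberkulmer", "Spelt", 3543, 44, 49, 60, 40),
    (12, "Speltvete Gotland", "Spelt", 2777, 37, 46, 58, 34),
    (15, "Svart emmer", "Primitive", 2525, 34, 45, 50, 33),
    (16, "T. monococcum", "Primitive", 2027, 28, 43, 51, 25),
    (2, "Aros", "Old cultivar", 4369, 34, 42, 64, 45),
    (3, "Aura", "Old cultivar", 4520, 37, 45, 64, 50),
    (5, "Erbe", "Old cultivar", 3938, 34, 42, 65, 47),
    (6, "Ertus", "Old cultivar", 4063, 41, 46, 66, 44),
    (7, "Hansa brun", "Old cultivar", 4269, 46, 46, 58, 46),
    (8, "Holger", "Old cultivar", 3754, 34, 44, 54, 44),
    (11, "Odin", "Old cultivar", 4572, 41, 47, 79, 47),
    (13, "Starke", "Old cultivar", 5307, 42, 52, 74, 56),
    (14, "Svale", "Old cultivar", 4912, 54, 48, 75, 53),
    (18, "Vakka", "Old cultivar", 3875, 33, 40, 51, 46),
    (19, "Walde", "Old cultivar", 4315, 44, 52, 64, 45),
]

# Published mean wholemeal concentrations (mg/kg) for the six genotypes the
# trial singled out for the cross-system nutrient-density comparison.
_STUDY_CONCENTRATIONS = {
    "Svale": {"Fe": 49.0, "Zn": 29.0, "Cu": 5.1, "Mg": 1202.0},
    "Starke": {"Fe": 34.6, "Zn": 29.2, "Cu": 4.7, "Mg": 1185.0},
    "Jacoby": {"Fe": 38.2, "Zn": 33.9, "Cu": 4.7, "Mg": 1225.0},
    "Walde": {"Fe": 43.9, "Zn": 36.4, "Cu": 5.1, "Mg": 1181.0},
    "Oberkulmer": {"Fe": 52.9, "Zn": 39.9, "Cu": 5.6, "Mg": 1302.0},
    "Speltvete Gotland": {"Fe": 58.0, "Zn": 50.0, "Cu": 7.1, "Mg": 1399.0},
}

# Externally published wheats grown under conventional (Sweden) or
# intensive (France) management: yield (kg/ha) and wholemeal mineral
# concentrations (mg/kg). None means not reported.
_LITERATURE_ROWS = [
    ("Akteur", "conventional_sweden", 6920, {"Fe": 38.0, "Zn": 26.4, "Cu": 3.8, "Mg": 1220.0}),
    ("Olivin", "conventional_sweden", 7180, {"Fe": 34.7, "Zn": 23.9, "Cu": 4.0, "Mg": 1260.0}),
    ("Fransaker", "conventional_sweden", 8190, {"Fe": 39.8, "Zn": 29.3, "Cu": 4.6, "Mg": 1110.0}),
    ("Elite modern (CF)", "intensive_france", 7510, {"Fe": 33.1, "Zn": 17.3, "Cu": None, "Mg": 1109.0}),
    ("Elite modern (LM)", "intensive_france", 10780, {"Fe": 39.1, "Zn": 22.9, "Cu": None, "Mg": 1006.0}),
    ("Elite modern (RE)", "intensive_france", 11560, {"Fe": 31.9, "Zn": 21.2, "Cu": None, "Mg": 894.0}),
]


def genotype_means() -> pd.DataFrame:
    """Published genotype-level three-year means of the reference trial.

    Returns a DataFrame indexed by genotype name with columns ``id``,
    ``group``, ``yield_kg_ha`` and ``ny_<mineral>`` (nutritional yield,
    adults·ha⁻¹·year⁻¹). Yields of the hulled groups are already on the
    dehulled (naked-grain) basis.
    """
    rows = []
    for gid, name, group, yld, fe, zn, cu, mg in _GENOTYPE_MEANS:
        rows.append(
            {
                "id": gid,
                "genotype": name,
                "group": group,
                "yield_kg_ha": float(yld),
                "ny_Fe": float(fe),
                "ny_Zn": float(zn),
                "ny_Cu": float(cu),
                "ny_Mg": float(mg),
            }
        )
    return pd.DataFrame(rows).set_index("genotype")


def study_concentrations() -> pd.DataFrame:
    """Published mean wholemeal concentrations (mg·kg⁻¹) of six study genotypes."""
    return pd.DataFrame(_STUDY_CONCENTRATIONS).T.loc[:, MINERALS]


def literature_rows() -> pd.DataFrame:
    """Externally published conventional/intensive wheats for comparison.

    Columns: ``system``, ``yield_kg_ha`` and one concentration column per
    mineral (mg·kg⁻¹, NaN where unreported). These rows are single
    published means, so nutritional yield for them is computed directly
    from (yield, concentration) rather than from plot-level data.
    """
    rows = []
    for name, system, yld, conc in _LITERATURE_ROWS:
        row = {"genotype": name, "system": system, "yield_kg_ha": float(yld)}
        for m in MINERALS:
            row[m] = conc[m] if conc[m] is not None else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("genotype")
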