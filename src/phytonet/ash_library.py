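"""Published compound library of *Artemisiae Scopariae* Herba (ASH) extract.

34 compounds identified from the herb extract by UFLC-ESI-Q/TOF-MS/MS,
with retention time, molecular formula, CAS number, the published
monoisotopic molecular weight, the measured [M+H]+ m/z and the published
ppm error.  Six of the compounds were picked out by bioaffinity
ultrafiltration against topoisomerase I (larger peak area with the enzyme
present than in the enzyme-free control) and are flagged as binders.

The published molecular-weight and ppm-error columns are carried only as
reference values for cross-checking; all theoretical masses used by the
package are recomputed from the formula column at run time.
"""

from __future__ import annotations

from .annotation import CompoundRecord, PeakRecord
from .formula import monoisotopic_mass, parse_formula

__all__ = [
    "ASH_COMPOUND_TABLE",
    "ASH_TOPO1_BINDERS",
    "ash_compound_library",
    "ash_measured_peaks",
]

# (name, category, rt_min, formula, cas, published_mw, measured_mh_mz, published_ppm)
ASH_COMPOUND_TABLE: list[tuple[str, str, float, str, str, float, float, float]] = [
    ("6-Hydroxy-7,8-dimethoxycoumarin", "Coumarin", 4.16, "C11H10O5", "107078-01-3", 222.0528, 223.0600, -0.4),
    ("Isoscopoletin", "Coumarin", 4.15, "C10H8O4", "776-86-3", 192.0423, 193.0497, 0.8),
    ("6,7-Dimethoxycoumarin", "Coumarin", 4.37, "C11H10O4", "120-08-1", 206.0579, 207.0650, -0.8),
    ("Kaempferol-3-O-rutinoside", "Flavone", 3.82, "C27H30O15", "17650-84-9", 594.1584, 595.1653, -0.8),
    ("Quercetin", "Flavone", 4.34, "C15H10O7", "117-39-5", 302.0427, 303.0498, -0.5),
    ("Luteolin", "Flavone", 4.53, "C15H10O6", "491-70-3", 286.0477, 287.0549, -0.3),
    ("Scutellarein", "Flavone", 4.53, "C15H10O6", "529-53-3", 286.0477, 287.0549, -0.3),
    ("Isorhamnetin", "Flavone", 4.58, "C16H12O7", "480-19-3", 316.0583, 317.0657, 0.4),
    ("5,7,3'-Trihydroxy-6,4',5'-trimethoxyflavone", "Flavone", 5.91, "C18H16O8", "78417-26-2", 360.0845, 361.0919, 0.3),
    ("Hydroxygenkwanin", "Flavone", 6.09, "C16H12O6", "20243-59-8", 300.0634, 301.0707, 0.1),
    ("Eupatilin", "Flavone", 6.52, "C18H16O7", "22368-21-4", 344.0896, 345.0969, 0.0),
    ("Genkwanin", "Flavone", 7.18, "C16H12O5", "437-64-9", 284.0685, 285.0758, 0.1),
    ("Irisflorentin", "Flavone", 7.30, "C20H18O8", "41743-73-1", 386.1002, 387.1077, 0.8),
    ("Phenylalanine", "Organic Acid", 2.84, "C9H11NO2", "63-91-2", 165.0790, 166.0864, 0.9),
    ("8-Epiloganic acid", "Organic Acid", 3.91, "C16H24O10", "82509-41-9", 376.1369, 377.1445, 0.7),
    ("Chlorogenic acid", "Organic Acid", 5.23, "C16H18O9", "327-97-9", 354.0951, 355.1022, -0.3),
    ("Linolenic acid", "Organic Acid", 10.70, "C18H30O2", "463-40-1", 278.2246, 279.2319, 0.1),
    ("alpha-Asarone", "Phenylpropanoid", 4.81, "C12H16O3", "2883-98-9", 208.1099, 209.1174, 1.0),
    ("Salidroside + NH3", "Phenyl glycoside", 3.45, "C14H20O7.NH3", "10338-51-9", 317.1475, 318.1546, -0.4),
    ("Sedanolide", "Phenphthalide", 7.23, "C12H18O2", "6415-59-4", 194.1307, 195.1381, 0.8),
    ("Aurantio-obtusin", "Anthraquinone", 6.01, "C17H14O7", "67979-25-3", 330.0739, 331.0809, -0.8),
    ("Ethyl vanillin", "Phenol", 3.59, "C9H10O3", "121-32-4", 166.0630, 167.0703, 0.5),
    ("Butylparaben", "Phenol", 4.88, "C11H14O3", "94-26-8", 194.0943, 195.1018, 1.0),
    ("6-Shogaol", "Phenol", 7.68, "C17H24O3", "555-66-8", 276.1725, 277.1799, 0.4),
    ("Genipin", "Terpene", 3.84, "C11H14O5", "6902-77-8", 226.0841, 227.0915, 0.3),
    ("Curcumenol", "Terpene", 7.10, "C15H22O2", "19431-84-6", 234.1620, 235.1692, -0.2),
    ("Linderane", "Terpene", 8.12, "C15H16O4", "13476-25-0", 260.1049, 261.1124, 1.0),
    ("Patchouli alcohol (loss H2O)", "Terpene", 8.21, "C15H24", "5986-55-0", 204.1878, 205.1950, -0.3),
    ("Anise oil", "Volatile oil", 4.81, "C10H12O", "4180-23-8", 148.0888, 149.0962, 0.5),
    ("Vitamin B6", "Alkaloid", 2.57, "C8H11NO3", "65-23-6", 169.0739, 170.0812, 0.2),
    ("Nicotinamide", "Alkaloid", 2.73, "C6H6N2O", "98-92-0", 122.0480, 123.0554, 0.8),
    ("Cordycepin", "Alkaloid", 3.20, "C10H13N5O3", "73-03-0", 251.1018, 252.1089, -0.9),
    ("Bicuculline", "Alkaloid", 3.71, "C20H17NO6", "485-49-4", 367.1056, 368.1125, -1.0),
    ("Piperine", "Alkaloid", 4.69, "C17H19NO3", "94-62-2", 285.1365, 286.1439, 0.4),
]

#: The six ultrafiltration-confirmed topoisomerase I binders.
ASH_TOPO1_BINDERS: frozenset[str] = frozenset(
    {
        "Eupatilin",
        "Isorhamnetin",
        "Luteolin",
        "Quercetin",
        "Chlorogenic acid",
        "Hydroxygenkwanin",
    }
)


def ash_compound_library() -> list[CompoundRecord]:
    """The 34-compound ASH library with masses recomputed from the formulas."""
    return [
        CompoundRecord.from_formula(name=name, category=category, formula_text=formula, cas=cas)
        for name, category, _rt, formula, cas, _mw, _mz, _ppm in ASH_COMPOUND_TABLE
    ]


def ash_measured_peaks(
    *,
    rng=None,
    enriched: frozenset[str] = ASH_TOPO1_BINDERS,
) -> list[PeakRecord]:
    """LC-MS peak table built from the measured [M+H]+ m/z values.

    Peak areas were not published, so sample/control areas are synthesized:
    compounds in ``enriched`` get a sample/control ratio drawn from
    U(1.5, 5), the rest from U(0.2, 0.95), reproducing the ultrafiltration
    contrast (6 of 34 enriched).  With ``rng=None`` the ratios are fixed at
    2.0 and 0.5.  Feature ids are ``F01``..``F34`` in elution-table order.
    """
    peaks = []
    for i, (name, _cat, rt, _formula, _cas, _mw, mz, _ppm) in enumerate(ASH_COMPOUND_TABLE, 1):
        if rng is None:
            control = 1.0e5
            ratio = 2.0 if name in enriched else 0.5
        else:
            control = rng.uniform(1.0e4, 1.0e6)
            ratio = rng.uniform(1.5, 5.0) if name in enriched else rng.uniform(0.2, 0.95)
        peaks.append(
            PeakRecord(
                feature_id=f"F{i:02d}",
                measured_mz=mz,
                retention_time=rt,
                area_sample=control * ratio,
                area_control=control,
            )
        )
    return peaks


def _verify_published_masses(tol_da: float = 5e-5) -> list[str]:
    """Names whose recomputed monoisotopic mass disagrees with the published
    molecular-weight column by more than ``tol_da`` (empty when consistent)."""
    bad = []
    for name, _cat, _rt, formula, _cas, mw, _mz, _ppm in ASH_COMPOUND_TABLE:
        if abs(monoisotopic_mass(parse_formula(formula)) - mw) > tol_da:
            bad.append(name)
    return bad
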