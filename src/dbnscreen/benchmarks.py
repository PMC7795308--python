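"""Published MDDR virtual-screening benchmark recall tables.

The MDDR (MDL Drug Data Report) benchmark is a licensed database of 102,516
bioactive compounds; it cannot be redistributed, so only the published
per-activity-class mean recall percentages (10 reference structures per
class, top 1% and 5% cutoffs) are embedded here as worked-example fixtures.
Three standard subsets are covered: DS1 (11 mixed-diversity activity
classes), DS2 (10 structurally homogeneous classes) and DS3 (10
heterogeneous classes).  Methods compared: the stacked-DBN reweighting
approach (SDBN), the Bayesian inference network (BIN), the quantum-based
similarity method (SQB), an adapted text-processing similarity measure
(ASMTP/ASMSC) and plain Tanimoto (TAN).

These numbers are evaluation-arithmetic inputs only (column means, gains,
best-in-class counts, Kendall W); nothing in the package treats them as
recomputable from data.
"""

from __future__ import annotations

from .fingerprint_io import ActivityClassSpec

__all__ = [
    "DS1_CLASSES", "DS2_CLASSES", "DS3_CLASSES",
    "RECALL_TABLES", "recall_table_frame",
]

#: activity classes (name, actives count, activity index) of the MDDR subsets
DS1_CLASSES = [
    ("Renin inhibitors", 1130, "31420"),
    ("HIV protease inhibitors", 750, "71523"),
    ("Thrombin inhibitors", 803, "37110"),
    ("Angiotensin II AT1 antagonists", 943, "31432"),
    ("Substance P antagonists", 1246, "42731"),
    ("5HT3 antagonist", 752, "06233"),
    ("5HT reuptake inhibitors", 359, "06245"),
    ("D2 antagonists", 395, "07701"),
    ("5HT1A agonists", 827, "06235"),
    ("Protein kinase C inhibitors", 453, "78374"),
    ("Cyclooxygenase inhibitors", 636, "78331"),
]

DS2_CLASSES = [
    ("Adenosine (A1) agonists", 207, "07707"),
    ("Adenosine (A2) agonists", 156, "07708"),
    ("Renin inhibitors", 1130, "31420"),
    ("CCK agonists", 111, "42710"),
    ("Monocyclic beta-lactams", 1346, "64100"),
    ("Cephalosporins", 113, "64200"),
    ("Carbacephems", 1051, "64220"),
    ("Carbapenems", 126, "64500"),
    ("Tribactams", 388, "64350"),
    ("Vitamin D analogous", 455, "75755"),
]

DS3_CLASSES = [
    ("Muscarinic (M1) agonists", 900, "09249"),
    ("NMDA receptor antagonists", 1400, "12455"),
    ("Nitric oxide synthase inhibitors", 505, "12464"),
    ("Dopamine beta-hydroxylase inhibitors", 106, "31281"),
    ("Aldose reductase inhibitors", 957, "43210"),
    ("Reverse transcriptase inhibitors", 700, "71522"),
    ("Aromatase inhibitors", 636, "75721"),
    ("Cyclooxygenase inhibitors", 636, "78331"),
    ("Phospholipase A2 inhibitors", 617, "78348"),
    ("Lipoxygenase inhibitors", 2111, "78351"),
]


def class_specs(classes) -> list[ActivityClassSpec]:
    """Activity-class sizes as :class:`ActivityClassSpec` objects."""
    return [ActivityClassSpec(idx, size) for _, size, idx in classes]


# per-class mean recall (%) by method; rows keyed by activity index
RECALL_TABLES: dict[tuple[str, float], dict[str, dict[str, float]]] = {
    ("DS1", 0.01): {
        "31420": {"SDBN": 74.21, "BIN": 74.08, "SQB": 73.73, "ASMSC": 73.84, "TAN": 69.69},
        "71523": {"SDBN": 27.97, "BIN": 28.26, "SQB": 26.84, "ASMSC": 15.03, "TAN": 25.94},
        "37110": {"SDBN": 26.03, "BIN": 26.05, "SQB": 24.73, "ASMSC": 20.82, "TAN": 9.63},
        "31432": {"SDBN": 39.79, "BIN": 39.23, "SQB": 36.66, "ASMSC": 37.14, "TAN": 35.82},
        "42731": {"SDBN": 23.06, "BIN": 21.68, "SQB": 21.17, "ASMSC": 19.53, "TAN": 17.77},
        "06233": {"SDBN": 19.29, "BIN": 14.06, "SQB": 12.49, "ASMSC": 10.35, "TAN": 13.87},
        "06245": {"SDBN": 6.27, "BIN": 6.31, "SQB": 6.03, "ASMSC": 5.5, "TAN": 6.51},
        "07701": {"SDBN": 14.05, "BIN": 11.45, "SQB": 11.35, "ASMSC": 7.99, "TAN": 8.63},
        "06235": {"SDBN": 12.87, "BIN": 10.84, "SQB": 10.15, "ASMSC": 9.94, "TAN": 9.71},
        "78374": {"SDBN": 17.47, "BIN": 14.25, "SQB": 13.08, "ASMSC": 13.9, "TAN": 13.69},
        "78331": {"SDBN": 9.93, "BIN": 6.03, "SQB": 5.92, "ASMSC": 6.89, "TAN": 7.17},
    },
    ("DS1", 0.05): {
        "31420": {"SDBN": 89.03, "BIN": 87.61, "SQB": 87.75, "ASMSC": 86.0, "TAN": 83.49},
        "71523": {"SDBN": 65.17, "BIN": 52.72, "SQB": 60.16, "ASMSC": 51.33, "TAN": 48.92},
        "37110": {"SDBN": 41.25, "BIN": 48.2, "SQB": 39.81, "ASMSC": 23.87, "TAN": 21.01},
        "31432": {"SDBN": 79.87, "BIN": 77.57, "SQB": 82.0, "ASMSC": 76.63, "TAN": 74.29},
        "42731": {"SDBN": 31.92, "BIN": 26.63, "SQB": 28.77, "ASMSC": 32.9, "TAN": 29.68},
        "06233": {"SDBN": 29.31, "BIN": 23.49, "SQB": 20.96, "ASMSC": 26.2, "TAN": 27.68},
        "06245": {"SDBN": 21.06, "BIN": 14.86, "SQB": 15.39, "ASMSC": 15.5, "TAN": 16.54},
        "07701": {"SDBN": 28.43, "BIN": 27.79, "SQB": 26.9, "ASMSC": 23.9, "TAN": 24.09},
        "06235": {"SDBN": 27.82, "BIN": 23.78, "SQB": 22.47, "ASMSC": 23.6, "TAN": 20.06},
        "78374": {"SDBN": 19.09, "BIN": 20.2, "SQB": 20.95, "ASMSC": 22.26, "TAN": 20.51},
        "78331": {"SDBN": 16.21, "BIN": 11.8, "SQB": 10.31, "ASMSC": 15.0, "TAN": 16.2},
    },
    ("DS2", 0.01): {
        "07707": {"SDBN": 83.19, "BIN": 72.18, "SQB": 72.09, "ASMSC": 67.86, "TAN": 61.84},
        "07708": {"SDBN": 94.82, "BIN": 96.0, "SQB": 95.68, "ASMSC": 97.87, "TAN": 47.03},
        "31420": {"SDBN": 79.27, "BIN": 79.82, "SQB": 78.56, "ASMSC": 73.51, "TAN": 65.1},
        "42710": {"SDBN": 74.81, "BIN": 76.27, "SQB": 76.82, "ASMSC": 81.17, "TAN": 81.27},
        "64100": {"SDBN": 93.65, "BIN": 88.43, "SQB": 87.8, "ASMSC": 86.62, "TAN": 80.31},
        "64200": {"SDBN": 71.16, "BIN": 70.18, "SQB": 70.18, "ASMSC": 69.11, "TAN": 53.84},
        "64220": {"SDBN": 68.71, "BIN": 68.32, "SQB": 67.58, "ASMSC": 66.26, "TAN": 38.64},
        "64500": {"SDBN": 75.62, "BIN": 81.2, "SQB": 79.2, "ASMSC": 46.24, "TAN": 30.56},
        "64350": {"SDBN": 85.21, "BIN": 81.89, "SQB": 81.68, "ASMSC": 68.01, "TAN": 80.18},
        "75755": {"SDBN": 96.52, "BIN": 98.06, "SQB": 98.02, "ASMSC": 93.48, "TAN": 87.56},
    },
    ("DS2", 0.05): {
        "07707": {"SDBN": 73.9, "BIN": 74.81, "SQB": 74.22, "ASMSC": 76.17, "TAN": 70.39},
        "07708": {"SDBN": 98.22, "BIN": 99.61, "SQB": 100.0, "ASMSC": 99.99, "TAN": 56.58},
        "31420": {"SDBN": 95.64, "BIN": 65.46, "SQB": 95.24, "ASMSC": 95.75, "TAN": 88.19},
        "42710": {"SDBN": 90.12, "BIN": 92.55, "SQB": 93.0, "ASMSC": 96.73, "TAN": 88.09},
        "64100": {"SDBN": 99.05, "BIN": 99.22, "SQB": 98.94, "ASMSC": 98.27, "TAN": 93.75},
        "64200": {"SDBN": 93.76, "BIN": 99.2, "SQB": 98.93, "ASMSC": 96.16, "TAN": 77.68},
        "64220": {"SDBN": 96.01, "BIN": 91.32, "SQB": 90.9, "ASMSC": 94.13, "TAN": 52.19},
        "64500": {"SDBN": 91.51, "BIN": 94.96, "SQB": 92.72, "ASMSC": 90.6, "TAN": 44.8},
        "64350": {"SDBN": 86.94, "BIN": 91.47, "SQB": 93.75, "ASMSC": 98.6, "TAN": 91.71},
        "75755": {"SDBN": 91.6, "BIN": 98.35, "SQB": 98.75, "ASMSC": 97.27, "TAN": 94.82},
    },
    ("DS3", 0.01): {
        "09249": {"SDBN": 19.47, "BIN": 15.33, "SQB": 10.99, "TAN": 12.12},
        "12455": {"SDBN": 13.29, "BIN": 9.37, "SQB": 7.03, "TAN": 6.57},
        "12464": {"SDBN": 12.91, "BIN": 8.45, "SQB": 6.92, "TAN": 8.17},
        "31281": {"SDBN": 23.62, "BIN": 18.29, "SQB": 18.67, "TAN": 16.95},
        "43210": {"SDBN": 14.23, "BIN": 7.34, "SQB": 6.83, "TAN": 6.27},
        "71522": {"SDBN": 11.92, "BIN": 4.08, "SQB": 6.57, "TAN": 3.75},
        "75721": {"SDBN": 29.08, "BIN": 20.41, "SQB": 20.38, "TAN": 17.32},
        "78331": {"SDBN": 11.93, "BIN": 7.51, "SQB": 6.16, "TAN": 6.31},
        "78348": {"SDBN": 9.17, "BIN": 9.79, "SQB": 8.99, "TAN": 10.15},
        "78351": {"SDBN": 18.13, "BIN": 13.68, "SQB": 12.5, "TAN": 9.84},
    },
    ("DS3", 0.05): {
        "09249": {"SDBN": 31.61, "BIN": 25.72, "SQB": 17.8, "TAN": 24.17},
        "12455": {"SDBN": 16.29, "BIN": 14.65, "SQB": 11.42, "TAN": 10.29},
        "12464": {"SDBN": 20.9, "BIN": 16.55, "SQB": 16.79, "TAN": 15.22},
        "31281": {"SDBN": 36.13, "BIN": 28.29, "SQB": 29.05, "TAN": 29.62},
        "43210": {"SDBN": 22.09, "BIN": 14.41, "SQB": 14.12, "TAN": 16.07},
        "71522": {"SDBN": 14.68, "BIN": 8.44, "SQB": 13.82, "TAN": 12.37},
        "75721": {"SDBN": 41.07, "BIN": 30.02, "SQB": 30.61, "TAN": 25.21},
        "78331": {"SDBN": 17.13, "BIN": 12.03, "SQB": 11.97, "TAN": 15.01},
        "78348": {"SDBN": 26.93, "BIN": 20.76, "SQB": 21.14, "TAN": 24.67},
        "78351": {"SDBN": 17.87, "BIN": 12.94, "SQB": 13.3, "TAN": 11.71},
    },
}


def recall_table_frame(dataset: str, cutoff: float):
    """Published per-class recalls as a classes x methods DataFrame."""
    import pandas as pd

    rows = RECALL_TABLES[(dataset, cutoff)]
    return pd.DataFrame.from_dict(rows, orient="index")
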