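"""Deterministic synthetic ICU-style cohort generator.

Emits the 12 core/event tables and 4 reference dictionaries with
referentially consistent keys (every event's admission exists, every ICD
code has a dictionary entry unless defects are injected), so each
pipeline stage is testable without credentialed hospital data.  Value
realism is schematic, not clinical: ICD codes come from a small bundled
dictionary, lab/chart items from bundled item lists with units.  The
point is structure — keys, joins, timestamps ordered admit < event <
discharge — not epidemiology.

The same spec and seed always produce byte-identical CSV files: every
table draws from its own seed-addressable substream, so adding rows to
one table never perturbs another.

Defect injection reproduces the failure modes the validation stage must
catch and log: malformed dates (the classic type-conversion error),
nulled required fields, and dictionary entries missing at join time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UnknownDefectError
from .schemas import SourceTable, TableSchema, register_default_schemas, write_table

_FMT = "%Y-%m-%d %H:%M:%S"

# --------------------------------------------------------------------------
# Bundled synthetic dictionaries (schematic stand-ins for hospital content)
# --------------------------------------------------------------------------

ICD_DIAGNOSES: tuple[tuple[str, int, str], ...] = (
    ("A011", 10, "Paratyphoid fever A"),
    ("I10", 10, "Essential (primary) hypertension"),
    ("E119", 10, "Type 2 diabetes mellitus without complications"),
    ("J189", 10, "Pneumonia, unspecified organism"),
    ("N179", 10, "Acute kidney failure, unspecified"),
    ("A419", 10, "Sepsis, unspecified organism"),
    ("K219", 10, "Gastro-esophageal reflux disease without esophagitis"),
    ("F329", 10, "Major depressive disorder, single episode, unspecified"),
    ("I2510", 10, "Atherosclerotic heart disease of native coronary artery"),
    ("E785", 10, "Hyperlipidemia, unspecified"),
    ("J449", 10, "Chronic obstructive pulmonary disease, unspecified"),
    ("D649", 10, "Anemia, unspecified"),
    ("I4891", 10, "Unspecified atrial fibrillation"),
    ("N390", 10, "Urinary tract infection, site not specified"),
    ("J9601", 10, "Acute respiratory failure with hypoxia"),
    ("E871", 10, "Hypo-osmolality and hyponatremia"),
    ("G4733", 10, "Obstructive sleep apnea"),
    ("I509", 10, "Heart failure, unspecified"),
    ("K7030", 10, "Alcoholic cirrhosis of liver without ascites"),
    ("E872", 10, "Acidosis"),
    ("R6521", 10, "Severe sepsis with septic shock"),
    ("I639", 10, "Cerebral infarction, unspecified"),
    ("C3490", 10, "Malignant neoplasm of unspecified part of bronchus or lung"),
    ("F059", 10, "Delirium due to known physiological condition"),
    ("L89154", 10, "Pressure ulcer of sacral region, stage 4"),
    ("4019", 9, "Unspecified essential hypertension"),
    ("42731", 9, "Atrial fibrillation"),
    ("4280", 9, "Congestive heart failure, unspecified"),
    ("5849", 9, "Acute kidney failure, unspecified"),
    ("25000", 9, "Diabetes mellitus without mention of complication"),
    ("51881", 9, "Acute respiratory failure"),
    ("5990", 9, "Urinary tract infection, site not specified"),
    ("2724", 9, "Other and unspecified hyperlipidemia"),
    ("486", 9, "Pneumonia, organism unspecified"),
    ("2859", 9, "Anemia, unspecified"),
    ("412", 9, "Old myocardial infarction"),
    ("53081", 9, "Esophageal reflux"),
    ("2449", 9, "Unspecified acquired hypothyroidism"),
    ("3051", 9, "Tobacco use disorder"),
    ("0389", 9, "Unspecified septicemia"),
    ("5070", 9, "Pneumonitis due to inhalation of food or vomitus"),
    ("78552", 9, "Septic shock"),
    ("2762", 9, "Acidosis"),
    ("496", 9, "Chronic airway obstruction, not elsewhere classified"),
    ("5845", 9, "Acute kidney failure with lesion of tubular necrosis"),
)

ICD_PROCEDURES: tuple[tuple[str, int, str], ...] = (
    ("3893", 9, "Venous catheterization, not elsewhere classified"),
    ("9604", 9, "Insertion of endotracheal tube"),
    ("9671", 9, "Continuous invasive mechanical ventilation for less than 96 consecutive hours"),
    ("9672", 9, "Continuous invasive mechanical ventilation for 96 consecutive hours or more"),
    ("3995", 9, "Hemodialysis"),
    ("8856", 9, "Coronary arteriography using two catheters"),
    ("0BH17EZ", 10, "Insertion of Endotracheal Airway into Trachea, Via Natural or Artificial Opening"),
    ("02HV33Z", 10, "Insertion of Infusion Device into Superior Vena Cava, Percutaneous Approach"),
    ("5A1945Z", 10, "Respiratory Ventilation, 24-96 Consecutive Hours"),
    ("5A1955Z", 10, "Respiratory Ventilation, Greater than 96 Consecutive Hours"),
    ("0W9G3ZZ", 10, "Drainage of Peritoneal Cavity, Percutaneous Approach"),
    ("3E0G76Z", 10, "Introduction of Nutritional Substance into Upper GI, Via Natural or Artificial Opening"),
)

#: (itemid, label, fluid, category, unit) — unit feeds labevents.valueuom
LAB_ITEMS: tuple[tuple[int, str, str, str, str], ...] = (
    (50802, "Base Excess", "Blood", "Blood Gas", "mEq/L"),
    (50820, "pH", "Blood", "Blood Gas", "units"),
    (50863, "Alkaline Phosphatase", "Blood", "Chemistry", "IU/L"),
    (50868, "Anion Gap", "Blood", "Chemistry", "mEq/L"),
    (50882, "Bicarbonate", "Blood", "Chemistry", "mEq/L"),
    (50893, "Calcium, Total", "Blood", "Chemistry", "mg/dL"),
    (50902, "Chloride", "Blood", "Chemistry", "mEq/L"),
    (50912, "Creatinine", "Blood", "Chemistry", "mg/dL"),
    (50931, "Glucose", "Blood", "Chemistry", "mg/dL"),
    (50960, "Magnesium", "Blood", "Chemistry", "mg/dL"),
    (50970, "Phosphate", "Blood", "Chemistry", "mg/dL"),
    (50971, "Potassium", "Blood", "Chemistry", "mEq/L"),
    (50983, "Sodium", "Blood", "Chemistry", "mEq/L"),
    (51006, "Urea Nitrogen", "Blood", "Chemistry", "mg/dL"),
    (51221, "Hematocrit", "Blood", "Hematology", "%"),
    (51222, "Hemoglobin", "Blood", "Hematology", "g/dL"),
    (51248, "MCH", "Blood", "Hematology", "pg"),
    (51265, "Platelet Count", "Blood", "Hematology", "K/uL"),
    (51279, "Red Blood Cells", "Blood", "Hematology", "m/uL"),
    (51301, "White Blood Cells", "Blood", "Hematology", "K/uL"),
)

#: (itemid, label, category, unit)
CHART_ITEMS: tuple[tuple[int, str, str, str], ...] = (
    (220045, "Heart Rate", "Routine Vital Signs", "bpm"),
    (220179, "Non Invasive Blood Pressure systolic", "Routine Vital Signs", "mmHg"),
    (220180, "Non Invasive Blood Pressure diastolic", "Routine Vital Signs", "mmHg"),
    (220181, "Non Invasive Blood Pressure mean", "Routine Vital Signs", "mmHg"),
    (220210, "Respiratory Rate", "Routine Vital Signs", "insp/min"),
    (220277, "O2 saturation pulseoxymetry", "Routine Vital Signs", "%"),
    (220621, "Glucose (serum)", "Labs", "mg/dL"),
    (223761, "Temperature Fahrenheit", "Routine Vital Signs", "°F"),
    (224639, "Daily Weight", "General", "kg"),
)

PROC_ITEMS: tuple[tuple[int, str, str, str], ...] = (
    (225792, "Invasive Ventilation", "Ventilation", "min"),
    (225794, "Non-invasive Ventilation", "Ventilation", "min"),
    (224385, "Intubation", "Intubation/Extubation", "min"),
    (225402, "EKG", "Procedures", "min"),
    (225459, "Chest X-Ray", "Imaging", "min"),
    (221214, "CT Scan", "Imaging", "min"),
)

INPUT_ITEMS: tuple[tuple[int, str, str, str], ...] = (
    (221906, "Norepinephrine", "Medications", "mg"),
    (221662, "Dopamine", "Medications", "mg"),
    (222168, "Propofol", "Medications", "mg"),
    (221744, "Fentanyl", "Medications", "mcg"),
    (225158, "NaCl 0.9%", "Fluids - Intravenous", "mL"),
    (220949, "Dextrose 5%", "Fluids - Intravenous", "mL"),
    (225975, "Heparin Sodium", "Medications", "units"),
    (225906, "Pantoprazole (Protonix)", "Medications", "mg"),
)

OUTPUT_ITEMS: tuple[tuple[int, str, str, str], ...] = (
    (226559, "Foley", "Output", "mL"),
    (226560, "Void", "Output", "mL"),
    (226575, "Chest Tube #1", "Output", "mL"),
    (226583, "Stool", "Output", "mL"),
    (226627, "OR Urine", "Output", "mL"),
)

PRESCRIPTION_DRUGS: tuple[tuple[str, float, str], ...] = (
    ("Acetaminophen", 500.0, "mg"),
    ("Aspirin", 81.0, "mg"),
    ("Metoprolol Tartrate", 25.0, "mg"),
    ("Furosemide", 40.0, "mg"),
    ("Insulin Human Regular", 10.0, "units"),
    ("Heparin", 5000.0, "units"),
    ("Vancomycin", 1000.0, "mg"),
    ("Pantoprazole", 40.0, "mg"),
    ("Lisinopril", 10.0, "mg"),
    ("Atorvastatin", 40.0, "mg"),
)

ADMISSION_TYPES = ("EW EMER.", "URGENT", "ELECTIVE", "OBSERVATION ADMIT", "SURGICAL SAME DAY ADMISSION")
DISCHARGE_LOCATIONS = ("HOME", "SKILLED NURSING FACILITY", "REHAB", "HOME HEALTH CARE", "HOSPICE")
CARE_UNITS = ("MICU", "SICU", "CCU", "Med/Surg", "Emergency Department")
MICRO_SPECIMENS = ("BLOOD CULTURE", "URINE", "SPUTUM", "SWAB")
MICRO_TESTS = ("Blood Culture, Routine", "Urine Culture", "Respiratory Culture", "Wound Culture")
MICRO_ORGS = ("ESCHERICHIA COLI", "STAPH AUREUS COAG +", "KLEBSIELLA PNEUMONIAE", "PSEUDOMONAS AERUGINOSA")

DEFECT_KINDS = ("bad_date", "null_required", "missing_dictionary")
#: defect kinds whose every injection must reject exactly one resource
REJECTING_DEFECTS = frozenset({"bad_date", "null_required"})

#: (table, timestamp column) cells eligible for bad_date injection
_BAD_DATE_TARGETS: tuple[tuple[str, str], ...] = (
    ("admissions", "admittime"),
    ("transfers", "intime"),
    ("chartevents", "charttime"),
    ("labevents", "charttime"),
    ("procedureevents", "starttime"),
    ("prescriptions", "starttime"),
    ("outputevents", "charttime"),
    ("microbiologyevents", "charttime"),
)

# substream indices so each table's randomness is independent
_STREAMS = {name: i for i, name in enumerate((
    "skeleton", "transfers", "diagnoses", "procedures_icd", "labevents",
    "chartevents", "procedureevents", "prescriptions", "inputevents",
    "microbiologyevents", "outputevents", "defects",
))}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Counts are inclusive (lo, hi) ranges drawn per patient/admission;
    defaults emulate a short ICU stay: 1-3 admissions per patient and a
    handful of events of each kind per admission.
    """

    n_patients: int = 100
    admissions_per_patient: tuple[int, int] = (1, 3)
    diagnoses_per_admission: tuple[int, int] = (1, 5)
    labevents_per_admission: tuple[int, int] = (2, 8)
    chartevents_per_admission: tuple[int, int] = (2, 6)
    procedureevents_per_admission: tuple[int, int] = (0, 2)
    procedures_icd_per_admission: tuple[int, int] = (0, 2)
    prescriptions_per_admission: tuple[int, int] = (1, 3)
    inputevents_per_admission: tuple[int, int] = (1, 3)
    microbiologyevents_per_admission: tuple[int, int] = (0, 2)
    outputevents_per_admission: tuple[int, int] = (1, 3)
    transfers_per_admission: tuple[int, int] = (1, 2)
    seed: int = 0
    error_injection: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        for name in (
            "admissions_per_patient", "diagnoses_per_admission", "labevents_per_admission",
            "chartevents_per_admission", "procedureevents_per_admission",
            "procedures_icd_per_admission", "prescriptions_per_admission",
            "inputevents_per_admission", "microbiologyevents_per_admission",
            "outputevents_per_admission", "transfers_per_admission",
        ):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a non-negative (lo, hi) range")
        if self.error_injection:
            for kind, rate in self.error_injection.items():
                if kind not in DEFECT_KINDS:
                    raise UnknownDefectError(f"unknown defect kind {kind!r}")
                if not (0.0 <= rate <= 1.0):
                    raise ConfigurationError(f"defect rate for {kind} must be in [0, 1]")


@dataclass
class CohortResult:
    tables: dict[str, SourceTable]
    truth: dict[str, int]  # ground-truth row counts per table
    defect_manifest: list[dict] = field(default_factory=list)

    @property
    def n_rejecting_defects(self) -> int:
        return sum(1 for d in self.defect_manifest if d["kind"] in REJECTING_DEFECTS)


def _fmt(dt: datetime) -> str:
    return dt.strftime(_FMT)


def _draw(rng: np.random.Generator, rng_pair: tuple[int, int]) -> int:
    lo, hi = rng_pair
    return int(rng.integers(lo, hi + 1))


def _event_times(rng: np.random.Generator, admit: datetime, disch: datetime, k: int,
                 n_items: int, unique_pairs: bool = False) -> list[tuple[datetime, int]]:
    """k (time, item index) draws strictly inside the stay; optionally unique."""
    total_minutes = max(int((disch - admit).total_seconds() // 60) - 2, 1)
    if unique_pairs:
        space = total_minutes * n_items
        k = min(k, space)
        flat = rng.choice(space, size=k, replace=False)
        out = [
            (admit + timedelta(minutes=1 + int(f) // n_items), int(f) % n_items)
            for f in sorted(flat.tolist())
        ]
        return out
    minutes = sorted(int(m) for m in rng.integers(1, total_minutes + 1, size=k))
    items = rng.integers(0, n_items, size=k)
    return [(admit + timedelta(minutes=m), int(i)) for m, i in zip(minutes, items)]


def generate_cohort(spec: CohortSpec) -> CohortResult:
    """Generate all 16 tables with referentially consistent keys."""
    schemas = register_default_schemas()
    year_start = datetime(2021, 1, 1)

    sk = _rng(spec.seed, "skeleton")
    patients_rows, admissions_rows = [], []
    admissions: list[dict] = []  # skeleton: subject, hadm, admit, disch
    hadm_seq = 2_000_000
    for i in range(spec.n_patients):
        subject_id = 10_000 + i
        gender = "M" if sk.random() < 0.5 else "F"
        anchor_age = int(sk.integers(18, 91))
        n_adm = _draw(sk, spec.admissions_per_patient)
        last_disch = None
        t_cursor = year_start + timedelta(days=int(sk.integers(0, 300)))
        for _ in range(n_adm):
            hadm_seq += 1
            admit = t_cursor + timedelta(hours=int(sk.integers(0, 48)))
            los_hours = int(sk.integers(24, 14 * 24))
            disch = admit + timedelta(hours=los_hours)
            t_cursor = disch + timedelta(days=int(sk.integers(1, 20)))
            admissions.append({"subject_id": subject_id, "hadm_id": hadm_seq,
                               "admit": admit, "disch": disch})
            admissions_rows.append({
                "subject_id": subject_id, "hadm_id": hadm_seq,
                "admittime": _fmt(admit), "dischtime": _fmt(disch),
                "admission_type": ADMISSION_TYPES[int(sk.integers(0, len(ADMISSION_TYPES)))],
                "discharge_location": DISCHARGE_LOCATIONS[int(sk.integers(0, len(DISCHARGE_LOCATIONS)))],
            })
            last_disch = disch
        died = n_adm > 0 and sk.random() < 0.06
        patients_rows.append({
            "subject_id": subject_id, "gender": gender, "anchor_age": anchor_age,
            "anchor_year": 2021,
            "dod": _fmt(last_disch) if died and last_disch else None,
        })

    tables_rows: dict[str, list[dict]] = {
        "patients": patients_rows, "admissions": admissions_rows,
        "transfers": [], "chartevents": [], "labevents": [], "procedureevents": [],
        "prescriptions": [], "inputevents": [], "microbiologyevents": [],
        "outputevents": [], "procedures_icd": [], "diagnoses_icd": [],
    }

    tr = _rng(spec.seed, "transfers")
    transfer_seq = 30_000_000
    for adm in admissions:
        k = _draw(tr, spec.transfers_per_admission)
        stay = (adm["disch"] - adm["admit"]) / max(k, 1)
        for j in range(k):
            transfer_seq += 1
            intime = adm["admit"] + stay * j
            outtime = adm["admit"] + stay * (j + 1)
            tables_rows["transfers"].append({
                "subject_id": adm["subject_id"], "hadm_id": adm["hadm_id"],
                "transfer_id": transfer_seq,
                "eventtype": "admit" if j == 0 else "transfer",
                "careunit": CARE_UNITS[int(tr.integers(0, len(CARE_UNITS)))],
                "intime": _fmt(intime),
                "outtime": _fmt(outtime),
            })

    dg = _rng(spec.seed, "diagnoses")
    for adm in admissions:
        k = min(_draw(dg, spec.diagnoses_per_admission), len(ICD_DIAGNOSES))
        picks = dg.choice(len(ICD_DIAGNOSES), size=k, replace=False)
        for seq, p in enumerate(sorted(picks.tolist()), start=1):
            code, ver, _title = ICD_DIAGNOSES[p]
            tables_rows["diagnoses_icd"].append({
                "subject_id": adm["subject_id"], "hadm_id": adm["hadm_id"],
                "seq_num": seq, "icd_code": code, "icd_version": ver,
            })

    pi = _rng(spec.seed, "procedures_icd")
    for adm in admissions:
        k = min(_draw(pi, spec.procedures_icd_per_admission), len(ICD_PROCEDURES))
        picks = pi.choice(len(ICD_PROCEDURES), size=k, replace=False)
        for seq, p in enumerate(sorted(picks.tolist()), start=1):
            code, ver, _title = ICD_PROCEDURES[p]
            tables_rows["procedures_icd"].append({
                "subject_id": adm["subject_id"], "hadm_id": adm["hadm_id"],
                "seq_num": seq, "chartdate": _fmt(adm["admit"].replace(hour=0, minute=0, second=0)),
                "icd_code": code, "icd_version": ver,
            })

    lb = _rng(spec.seed, "labevents")
    labevent_seq = 1_000_000
    for adm in admissions:
        k = _draw(lb, spec.labevents_per_admission)
        for when, idx in _event_times(lb, adm["admit"], adm["disch"], k, len(LAB_ITEMS)):
            labevent_seq += 1
            itemid, _label, _fluid, _cat, unit = LAB_ITEMS[idx]
            tables_rows["labevents"].append({
                "labevent_id": labevent_seq, "subject_id": adm["subject_id"],
                "hadm_id": adm["hadm_id"], "itemid": itemid, "charttime": _fmt(when),
                "valuenum": round(float(lb.uniform(0.5, 200.0)), 1), "valueuom": unit,
            })

    ch = _rng(spec.seed, "chartevents")
    for adm in admissions:
        k = _draw(ch, spec.chartevents_per_admission)
        for when, idx in _event_times(ch, adm["admit"], adm["disch"], k,
                                      len(CHART_ITEMS), unique_pairs=True):
            itemid, _label, _cat, unit = CHART_ITEMS[idx]
            tables_rows["chartevents"].append({
                "subject_id": adm["subject_id"], "hadm_id": adm["hadm_id"],
                "charttime": _fmt(when), "itemid": itemid,
                "valuenum": round(float(ch.uniform(20.0, 180.0)), 1), "valueuom": unit,
            })

    pe = _rng(spec.seed, "procedureevents")
    order_seq = 5_000_000
    for adm in admissions:
        k = _draw(pe, spec.procedureevents_per_admission)
        for when, idx in _event_times(pe, adm["admit"], adm["disch"], k, len(PROC_ITEMS)):
            order_seq += 1
            itemid = PROC_ITEMS[idx][0]
            tables_rows["procedureevents"].append({
                "orderid": order_seq, "subject_id": adm["subject_id"],
                "hadm_id": adm["hadm_id"], "starttime": _fmt(when),
                "endtime": _fmt(when + timedelta(minutes=int(pe.integers(10, 240)))),
                "itemid": itemid,
            })

    rx = _rng(spec.seed, "prescriptions")
    pharmacy_seq = 7_000_000
    for adm in admissions:
        k = _draw(rx, spec.prescriptions_per_admission)
        for when, idx in _event_times(rx, adm["admit"], adm["disch"], k,
                                      len(PRESCRIPTION_DRUGS)):
            pharmacy_seq += 1
            drug, dose, unit = PRESCRIPTION_DRUGS[idx]
            tables_rows["prescriptions"].append({
                "pharmacy_id": pharmacy_seq, "subject_id": adm["subject_id"],
                "hadm_id": adm["hadm_id"], "drug": drug, "starttime": _fmt(when),
                "dose_val_rx": dose, "dose_unit_rx": unit,
            })

    iv = _rng(spec.seed, "inputevents")
    for adm in admissions:
        k = _draw(iv, spec.inputevents_per_admission)
        for when, idx in _event_times(iv, adm["admit"], adm["disch"], k, len(INPUT_ITEMS)):
            order_seq += 1
            itemid, _label, _cat, unit = INPUT_ITEMS[idx]
            tables_rows["inputevents"].append({
                "orderid": order_seq, "subject_id": adm["subject_id"],
                "hadm_id": adm["hadm_id"], "starttime": _fmt(when),
                "endtime": _fmt(when + timedelta(minutes=int(iv.integers(15, 480)))),
                "itemid": itemid,
                "amount": round(float(iv.uniform(1.0, 500.0)), 1), "amountuom": unit,
            })

    mb = _rng(spec.seed, "microbiologyevents")
    micro_seq = 9_000_000
    for adm in admissions:
        k = _draw(mb, spec.microbiologyevents_per_admission)
        for when, idx in _event_times(mb, adm["admit"], adm["disch"], k, len(MICRO_TESTS)):
            micro_seq += 1
            has_org = mb.random() < 0.6
            tables_rows["microbiologyevents"].append({
                "microevent_id": micro_seq, "subject_id": adm["subject_id"],
                "hadm_id": adm["hadm_id"], "charttime": _fmt(when),
                "spec_type_desc": MICRO_SPECIMENS[idx % len(MICRO_SPECIMENS)],
                "test_name": MICRO_TESTS[idx],
                "org_name": MICRO_ORGS[int(mb.integers(0, len(MICRO_ORGS)))] if has_org else None,
                "interpretation": ("S" if mb.random() < 0.7 else "R") if has_org else None,
            })

    ot = _rng(spec.seed, "outputevents")
    for adm in admissions:
        k = _draw(ot, spec.outputevents_per_admission)
        for when, idx in _event_times(ot, adm["admit"], adm["disch"], k,
                                      len(OUTPUT_ITEMS), unique_pairs=True):
            itemid, _label, _cat, unit = OUTPUT_ITEMS[idx]
            tables_rows["outputevents"].append({
                "subject_id": adm["subject_id"], "hadm_id": adm["hadm_id"],
                "charttime": _fmt(when), "itemid": itemid,
                "value": round(float(ot.uniform(10.0, 800.0)), 1), "valueuom": unit,
            })

    # reference dictionaries (full bundled content, deterministic order)
    dict_rows = {
        "d_items": [
            {"itemid": i, "label": lab, "category": cat, "unitname": unit}
            for i, lab, cat, unit in sorted(CHART_ITEMS + PROC_ITEMS + INPUT_ITEMS + OUTPUT_ITEMS)
        ],
        "d_labitems": [
            {"itemid": i, "label": lab, "fluid": fl, "category": cat}
            for i, lab, fl, cat, _u in LAB_ITEMS
        ],
        "d_icd_procedures": [
            {"icd_code": c, "icd_version": v, "long_title": t} for c, v, t in ICD_PROCEDURES
        ],
        "d_icd_diagnoses": [
            {"icd_code": c, "icd_version": v, "long_title": t} for c, v, t in ICD_DIAGNOSES
        ],
    }

    tables: dict[str, SourceTable] = {}
    for name, rows in list(tables_rows.items()) + list(dict_rows.items()):
        schema = schemas[name]
        frame = pd.DataFrame(rows, columns=list(schema.column_names))
        frame = _apply_kinds(frame, schema)
        tables[name] = SourceTable(schema, frame)

    truth = {name: tab.n_rows for name, tab in tables.items()}
    manifest: list[dict] = []
    if spec.error_injection:
        tables, manifest = inject_defects(tables, spec.error_injection, spec.seed)
    return CohortResult(tables=tables, truth=truth, defect_manifest=manifest)


def _apply_kinds(frame: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    out = {}
    for col in schema.columns:
        s = frame[col.name] if col.name in frame else pd.Series([], dtype="object")
        if col.kind == "integer":
            out[col.name] = s.astype("Int64")
        elif col.kind == "decimal":
            out[col.name] = s.astype("float64")
        else:
            out[col.name] = s.astype("object").where(s.notna(), other=None)
    return pd.DataFrame(out)


def inject_defects(
    tables: dict[str, SourceTable],
    error_injection: dict[str, float],
    seed: int,
) -> tuple[dict[str, SourceTable], list[dict]]:
    """Reproducibly corrupt tables; returns (tables, manifest of mutations).

    At most one defect lands on any given row, so each ``bad_date`` or
    ``null_required`` manifest entry accounts for exactly one resource
    later rejected at validation.  ``missing_dictionary`` removes
    dictionary rows, which downstream becomes null descriptive columns
    after the join (logged, not rejected).
    """
    for kind, rate in error_injection.items():
        if kind not in DEFECT_KINDS:
            raise UnknownDefectError(f"unknown defect kind {kind!r}")
        if not (0.0 <= rate <= 1.0):
            raise ConfigurationError(f"defect rate for {kind} must be in [0, 1]")
    rng = _rng(seed, "defects")
    frames = {name: tab.frame.copy() for name, tab in tables.items()}
    manifest: list[dict] = []
    mutated: set[tuple[str, int]] = set()
    counter = 0

    rate = error_injection.get("bad_date", 0.0)
    if rate > 0:
        for table, column in _BAD_DATE_TARGETS:
            frame = frames[table]
            hits = rng.random(len(frame)) < rate
            for ridx in np.flatnonzero(hits):
                ridx = int(ridx)
                if (table, ridx) in mutated:
                    continue
                counter += 1
                # malformed calendar date; unique suffix keeps composite keys distinct
                frame.iat[ridx, frame.columns.get_loc(column)] = f"2023-13-40 00:00:00.{counter}"
                mutated.add((table, ridx))
                manifest.append({"table": table, "row": ridx, "column": column, "kind": "bad_date"})

    rate = error_injection.get("null_required", 0.0)
    if rate > 0:
        frame = frames["inputevents"]
        hits = rng.random(len(frame)) < rate
        for ridx in np.flatnonzero(hits):
            ridx = int(ridx)
            if ("inputevents", ridx) in mutated:
                continue
            # null the whole administration window: effective[x] is required
            frame.iat[ridx, frame.columns.get_loc("starttime")] = None
            frame.iat[ridx, frame.columns.get_loc("endtime")] = None
            mutated.add(("inputevents", ridx))
            manifest.append({"table": "inputevents", "row": ridx,
                             "column": "starttime", "kind": "null_required"})

    rate = error_injection.get("missing_dictionary", 0.0)
    if rate > 0:
        frame = frames["d_icd_diagnoses"]
        used = set(
            zip(frames["diagnoses_icd"]["icd_code"], frames["diagnoses_icd"]["icd_version"])
        )
        drop_idx = []
        for ridx in range(len(frame)):
            key = (frame.iat[ridx, 0], frame.iat[ridx, 1])
            if key in used and rng.random() < rate:
                drop_idx.append(ridx)
                manifest.append({"table": "d_icd_diagnoses", "row": ridx,
                                 "column": "*", "kind": "missing_dictionary"})
        frames["d_icd_diagnoses"] = frame.drop(index=drop_idx).reset_index(drop=True)

    out = {name: SourceTable(tables[name].schema, frame) for name, frame in frames.items()}
    return out, manifest


def write_cohort(result: CohortResult, out_dir: str | Path) -> Path:
    """Write every table as ``<out_dir>/<table>.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, tab in result.tables.items():
        write_table(tab, out_dir / f"{name}.csv")
    return out_dir


def generate_to_dir(spec: CohortSpec, out_dir: str | Path) -> CohortResult:
    result = generate_cohort(spec)
    write_cohort(result, out_dir)
    return result
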