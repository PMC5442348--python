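"""Term bank backing the synthetic report generator and example vocabularies.

Diseases with common abbreviations, medications with their drug class
(hypernym) and disease inductions, coronary artery phrases, and stenosis
severities — all cardiology-flavored so the synthetic corpora read like the
catheterization / angiography / clinic-note material the engine targets.
"""

from __future__ import annotations

#: (canonical, [abbreviations/synonyms])
DISEASES: list[tuple[str, list[str]]] = [
    ("Diabetes Mellitus", ["DM", "Diabetes"]),
    ("Hypertension", ["HTN"]),
    ("Hyperlipidemia", ["HLD"]),
    ("Coronary Artery Disease", ["CAD"]),
    ("Myocardial Infarction", ["MI"]),
    ("Congestive Heart Failure", ["CHF"]),
    ("Atrial Fibrillation", ["AF", "AFib"]),
    ("Chronic Kidney Disease", ["CKD"]),
    ("Chronic Obstructive Pulmonary Disease", ["COPD"]),
    ("Obstructive Sleep Apnea", ["OSA"]),
    ("Peripheral Artery Disease", ["PAD"]),
    ("Gastroesophageal Reflux Disease", ["GERD"]),
    ("Cerebrovascular Accident", ["CVA"]),
    ("Transient Ischemic Attack", ["TIA"]),
    ("Aortic Stenosis", []),
    ("Mitral Regurgitation", []),
    ("Cardiomyopathy", []),
    ("Hypothyroidism", []),
    ("Anemia", []),
    ("Asthma", []),
    ("Osteoarthritis", ["OA"]),
    ("Depression", []),
    ("Obesity", []),
    ("Gout", []),
    ("Cancer", []),
]

#: (canonical, drug class hypernym or None, [(induced attribute, induced value)])
MEDICATIONS: list[tuple[str, str | None, list[tuple[str, str]]]] = [
    ("Metformin", "oral hypoglycemic", [("disease", "Diabetes Mellitus")]),
    ("Insulin", None, [("disease", "Diabetes Mellitus")]),
    ("Pindolol", "beta blocker", []),
    ("Metoprolol", "beta blocker", []),
    ("Atenolol", "beta blocker", []),
    ("Carvedilol", "beta blocker", []),
    ("Propranolol", "beta blocker", []),
    ("Lisinopril", "ACE inhibitor", []),
    ("Captopril", "ACE inhibitor", []),
    ("Enalapril", "ACE inhibitor", []),
    ("Ramipril", "ACE inhibitor", []),
    ("Losartan", "ARB", []),
    ("Valsartan", "ARB", []),
    ("Atorvastatin", "statin", []),
    ("Simvastatin", "statin", []),
    ("Rosuvastatin", "statin", []),
    ("Pravastatin", "statin", []),
    ("Furosemide", "diuretic", []),
    ("Hydrochlorothiazide", "diuretic", []),
    ("Spironolactone", "diuretic", []),
    ("Aspirin", "antiplatelet", []),
    ("Clopidogrel", "antiplatelet", []),
    ("Ticagrelor", "antiplatelet", []),
    ("Warfarin", "anticoagulant", []),
    ("Apixaban", "anticoagulant", []),
    ("Rivaroxaban", "anticoagulant", []),
    ("Amlodipine", "calcium channel blocker", []),
    ("Diltiazem", "calcium channel blocker", []),
    ("Verapamil", "calcium channel blocker", []),
    ("Nitroglycerin", "nitrate", []),
    ("Isosorbide Mononitrate", "nitrate", []),
    ("Omeprazole", "proton pump inhibitor", []),
    ("Pantoprazole", "proton pump inhibitor", []),
    ("Levothyroxine", "thyroid hormone", []),
    ("Gabapentin", None, []),
    ("Albuterol", "bronchodilator", []),
    ("Amiodarone", "antiarrhythmic", []),
    ("Digoxin", None, []),
]

#: drug-class terms carried in the medication vocabulary in their own right
#: ("statin intolerant" must be recognizable — and vetoable)
MEDICATION_CLASS_TERMS: list[str] = ["statin", "beta blocker", "ACE inhibitor"]

ARTERIES: list[str] = [
    "right coronary artery",
    "left main coronary artery",
    "left anterior descending artery",
    "proximal left anterior descending artery",
    "left circumflex artery",
    "right posterior descending artery",
    "first diagonal branch",
    "second diagonal branch",
    "first obtuse marginal branch",
    "second obtuse marginal branch",
    "ramus intermedius",
    "posterior lateral branch",
]

SEVERITIES: list[str] = ["minimal", "mild", "moderate", "severe", "critical"]

ACCESS_SITES: list[str] = ["femoral", "radial", "brachial"]

OCCUPATIONS: list[str] = ["teacher", "carpenter", "nurse", "accountant",
                          "farmer", "engineer", "retired postal worker"]
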