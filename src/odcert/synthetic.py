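"""Synthetic death-certificate generator.

Real coded death-certificate data is restricted, so this module generates
labeled certificates with the statistical structure the classification
task assumes: terse, fully capitalized certifier language; ~3% overdose
prevalence; overdose records whose cause/injury text follows common
certifier patterns ("ACUTE <drug> TOXICITY", "<drug> OVERDOSE", "MIXED
DRUG INTOXICATION", ...) with an underlying-cause code drawn from the
overdose ICD-10 ranges; and non-overdose records drawn from natural- and
external-cause templates with matching codes.

Two deliberate difficulty mechanisms mirror the failure modes of
real-world surveillance text:

* **SCC confounding** — a fraction of non-overdose records mention a
  *prior* overdose in the "significant conditions contributing" section
  only (the death itself was not an overdose).  These records make the
  ALL_SECTIONS feature space noisier than NO_SCC, so excluding SCC should
  improve positive predictive value.
* **Novel substances** — passing ``novel_drugs`` (test-year generation)
  introduces substance names absent from the training year, penalizing
  exact-phrase rule lists while context n-grams still generalize.

Everything is drawn from a single seeded generator, so output is
byte-identical across runs for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .certificates import DeathCertificate, label_from_ucod
from .errors import ValidationError

__all__ = ["GeneratorConfig", "DEFAULT_DRUG_LEXICON", "generate"]

#: Substances commonly named on overdose certificates.
DEFAULT_DRUG_LEXICON = (
    "HEROIN",
    "FENTANYL",
    "COCAINE",
    "METHAMPHETAMINE",
    "OXYCODONE",
    "ALPRAZOLAM",
    "ETHANOL",
)

# (cause_a template, due-to template or "", weight).  "{d}"/"{d2}" are
# substance slots.  The "TOXIC EFFECTS" pattern names only the substance,
# so exact-phrase rule lists can miss it when the substance is novel.
_OD_CAUSE_TEMPLATES = (
    ("ACUTE {d} TOXICITY", "", 0.25),
    ("ACUTE COMBINED {d} AND {d2} TOXICITY", "", 0.10),
    ("{d} OVERDOSE", "", 0.20),
    ("MIXED DRUG INTOXICATION", "", 0.10),
    ("ACUTE RESPIRATORY FAILURE", "DRUG OVERDOSE", 0.10),
    ("TOXIC EFFECTS OF {d}", "", 0.25),
)

_OD_INJURY_TEMPLATES = (
    ("ACCIDENTAL OVERDOSE", 0.35),
    ("SUBSTANCE INGESTION", 0.20),
    ("FOUND UNRESPONSIVE AT RESIDENCE", 0.25),
    ("", 0.20),
)

# Unintentional codes dominate real overdose mortality.
_OD_UCOD_PREFIXES = (
    (("X40", "X41", "X42", "X43", "X44"), 0.85),
    (("X60", "X61", "X62", "X63", "X64"), 0.08),
    (("X85",), 0.01),
    (("Y10", "Y11", "Y12", "Y13", "Y14"), 0.06),
)

# cause_a, cause_b, cause_c, ucod prefix, injury description
_NEG_TEMPLATES = (
    ("ACUTE MYOCARDIAL INFARCTION", "ATHEROSCLEROTIC CARDIOVASCULAR DISEASE", "", "I21", ""),
    ("CONGESTIVE HEART FAILURE", "ISCHEMIC CARDIOMYOPATHY", "", "I50", ""),
    ("METASTATIC LUNG CANCER", "", "", "C34", ""),
    ("CHRONIC OBSTRUCTIVE PULMONARY DISEASE", "", "", "J44", ""),
    ("SEPSIS", "PNEUMONIA", "", "A41", ""),
    ("ACUTE RESPIRATORY FAILURE", "", "", "J96", ""),
    ("CEREBROVASCULAR ACCIDENT", "HYPERTENSION", "", "I63", ""),
    ("ALZHEIMERS DEMENTIA", "", "", "G30", ""),
    ("END STAGE RENAL DISEASE", "DIABETES MELLITUS", "", "N18", ""),
    ("ALCOHOLIC CIRRHOSIS OF LIVER", "", "", "K70", ""),
    ("BLUNT FORCE INJURIES OF HEAD AND TORSO", "", "", "V43", "DRIVER IN MOTOR VEHICLE COLLISION"),
    ("HANGING", "", "", "X70", "SUICIDE BY HANGING AT RESIDENCE"),
    ("GUNSHOT WOUND OF HEAD", "", "", "X74", "SELF INFLICTED GUNSHOT WOUND"),
    ("COMPLICATIONS OF HIP FRACTURE", "", "", "W19", "FALL AT NURSING HOME"),
)

_SCC_POOL = (
    "HYPERTENSION",
    "DIABETES MELLITUS",
    "OBESITY",
    "TOBACCO USE",
    "ATRIAL FIBRILLATION",
    "HYPERLIPIDEMIA",
    "CORONARY ARTERY DISEASE",
    "CHRONIC KIDNEY DISEASE",
)

_OD_SCC_EXTRAS = (
    "CHRONIC SUBSTANCE ABUSE",
    "INTRAVENOUS DRUG USE",
    "HEPATITIS C",
)

# Mentions of a *previous* overdose appended to the SCC of non-overdose
# records; some are indistinguishable from causal mentions by bag of words.
_CONFOUNDER_PHRASES = (
    "HISTORY OF DRUG OVERDOSE",
    "PRIOR HEROIN OVERDOSE",
    "REMOTE METHAMPHETAMINE OVERDOSE",
    "DRUG OVERDOSE",
)

_ABBREVIATIONS = {
    "MYOCARDIAL INFARCTION": "MI",
    "CHRONIC OBSTRUCTIVE PULMONARY DISEASE": "COPD",
    "CONGESTIVE HEART FAILURE": "CHF",
    "CORONARY ARTERY DISEASE": "CAD",
    "HYPERTENSION": "HTN",
    "DIABETES MELLITUS": "DM",
    "MOTOR VEHICLE COLLISION": "MVC",
    "CEREBROVASCULAR ACCIDENT": "CVA",
    "ETHANOL": "ETOH",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one generated cohort.

    ``od_prevalence`` defaults to the ~3% overdose share of all deaths;
    ``scc_confounder_rate`` is the fraction of non-overdose records whose
    SCC mentions a prior overdose; ``template_noise`` is the per-record
    probability of one text perturbation (word drop, word duplication, or
    abbreviation substitution); ``novel_drugs`` adds substances (e.g. an
    emerging designer drug) to the lexicon used for overdose text, for
    test-year generation.
    """

    n: int
    od_prevalence: float = 0.03
    scc_confounder_rate: float = 0.05
    drug_lexicon: tuple[str, ...] = DEFAULT_DRUG_LEXICON
    template_noise: float = 0.05
    seed: int = 0
    novel_drugs: tuple[str, ...] = ()
    novel_drug_share: float = 0.3
    id_prefix: str = "DC"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for name in ("od_prevalence", "scc_confounder_rate", "template_noise", "novel_drug_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not self.drug_lexicon:
            raise ValidationError("drug_lexicon must be nonempty")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "od_prevalence": self.od_prevalence,
            "scc_confounder_rate": self.scc_confounder_rate,
            "drug_lexicon": list(self.drug_lexicon),
            "template_noise": self.template_noise,
            "seed": self.seed,
            "novel_drugs": list(self.novel_drugs),
            "novel_drug_share": self.novel_drug_share,
            "id_prefix": self.id_prefix,
        }


def _weighted(rng: np.random.Generator, options: Sequence[tuple]) -> tuple:
    weights = np.array([o[-1] for o in options], dtype=float)
    i = rng.choice(len(options), p=weights / weights.sum())
    return options[i]


def _pick_drug(rng: np.random.Generator, cfg: GeneratorConfig, exclude: str = "") -> str:
    if cfg.novel_drugs and rng.random() < cfg.novel_drug_share:
        pool = [d for d in cfg.novel_drugs if d != exclude] or list(cfg.novel_drugs)
    else:
        pool = [d for d in cfg.drug_lexicon if d != exclude] or list(cfg.drug_lexicon)
    return pool[rng.integers(len(pool))]


def _od_ucod(rng: np.random.Generator) -> str:
    prefixes, _ = _weighted(rng, _OD_UCOD_PREFIXES)
    code = prefixes[rng.integers(len(prefixes))]
    if rng.random() < 0.7:
        code += str(rng.integers(10))
    return code


def _apply_noise(rng: np.random.Generator, dc: DeathCertificate) -> None:
    fields = [f for f in ("cause_a", "cause_b", "scc", "injury_desc") if getattr(dc, f)]
    if not fields:
        return
    name = fields[rng.integers(len(fields))]
    text = getattr(dc, name)
    op = rng.integers(3)
    if op == 0:  # abbreviation substitution
        for long, short in _ABBREVIATIONS.items():
            if long in text:
                text = text.replace(long, short)
                break
        else:
            op = 1
    if op == 1:  # duplicate a word (stutter, common in transcribed text)
        words = text.split()
        i = int(rng.integers(len(words)))
        words.insert(i, words[i])
        text = " ".join(words)
    elif op == 2:  # drop a word
        words = text.split()
        if len(words) > 1:
            del words[rng.integers(len(words))]
            text = " ".join(words)
    setattr(dc, name, text)


def _generate_od(rng: np.random.Generator, cfg: GeneratorConfig) -> DeathCertificate:
    cause_tpl, due_tpl, _ = _weighted(rng, _OD_CAUSE_TEMPLATES)
    d = _pick_drug(rng, cfg)
    d2 = _pick_drug(rng, cfg, exclude=d)
    cause_a = cause_tpl.format(d=d, d2=d2)
    cause_b = due_tpl.format(d=d, d2=d2) if due_tpl else ""
    injury, _ = _weighted(rng, _OD_INJURY_TEMPLATES)
    scc = ""
    r = rng.random()
    if r < 0.15:
        scc = _OD_SCC_EXTRAS[rng.integers(len(_OD_SCC_EXTRAS))]
    elif r < 0.35:
        scc = ", ".join(
            rng.choice(_SCC_POOL, size=rng.integers(1, 3), replace=False)
        )
    return DeathCertificate(
        cause_a=cause_a, cause_b=cause_b, scc=scc, injury_desc=injury, ucod=_od_ucod(rng)
    )


def _generate_non_od(rng: np.random.Generator, cfg: GeneratorConfig) -> DeathCertificate:
    cause_a, cause_b, cause_c, prefix, injury = _NEG_TEMPLATES[
        rng.integers(len(_NEG_TEMPLATES))
    ]
    ucod = prefix + (str(rng.integers(10)) if rng.random() < 0.7 else "")
    scc = ""
    if rng.random() < 0.5:
        scc = ", ".join(
            rng.choice(_SCC_POOL, size=rng.integers(1, 3), replace=False)
        )
    if rng.random() < cfg.scc_confounder_rate:
        confounder = _CONFOUNDER_PHRASES[rng.integers(len(_CONFOUNDER_PHRASES))]
        scc = f"{scc}, {confounder}" if scc else confounder
    return DeathCertificate(
        cause_a=cause_a,
        cause_b=cause_b,
        cause_c=cause_c,
        scc=scc,
        injury_desc=injury,
        ucod=ucod,
    )


def generate(cfg: GeneratorConfig) -> list[DeathCertificate]:
    """Generate ``cfg.n`` labeled certificates, deterministic in ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    records: list[DeathCertificate] = []
    for i in range(cfg.n):
        is_od = bool(rng.random() < cfg.od_prevalence)
        dc = _generate_od(rng, cfg) if is_od else _generate_non_od(rng, cfg)
        if rng.random() < cfg.template_noise:
            _apply_noise(rng, dc)
        dc.id = f"{cfg.id_prefix}{i:06d}"
        dc.label = label_from_ucod(dc.ucod)
        records.append(dc)
    return records
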