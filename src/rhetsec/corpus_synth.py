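"""Synthetic abstract corpora and simulated sentence embeddings.

Medical abstracts are written in four rhetorical sections — objective,
methods, results, conclusion — and sentences from each section carry
characteristic discourse cues ("aimed to investigate", "were randomly
assigned", "increased significantly", "these findings suggest").  This
module generates labelled corpora with exactly that structure, in
Chinese or English, from seeded template banks: every abstract draws a
topic tuple (condition, intervention, outcome, population) and renders a
few sentences per section from class-specific templates filled with that
shared topic.  Because the topic is shared across an abstract's four
sections, the literal content of sentences within one abstract overlaps
heavily while the functional cues differ by section — the signal
structure a rhetorical-section classifier must exploit.

The embedding simulator provides a second, purely geometric stand-in:
a 4-component mixture of spherical Gaussians projected to the unit
sphere, with a single knob controlling angular separation of the class
means.  It is used to benchmark the clustering and supervised stages at
a controlled, known difficulty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

CLASSES = ("objective", "methods", "results", "conclusion")
LANGUAGES = ("zh", "en")

__all__ = [
    "CLASSES",
    "LANGUAGES",
    "SentenceRecord",
    "CorpusSpec",
    "EmbeddingSimSpec",
    "generate_abstract_corpus",
    "generate_duplicate_pairs",
    "simulate_embeddings",
    "split_corpus",
]


# ---------------------------------------------------------------------------
# Records and specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SentenceRecord:
    """One abstract sentence with an optional rhetorical-section label."""

    text: str
    abstract_id: str
    sentence_index: int
    label: str | None = None

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError("SentenceRecord.text must be nonempty")
        if self.sentence_index < 0:
            raise ValueError("sentence_index must be >= 0")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASSES}")


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a synthetic corpus: per-class sentence counts, language,
    optional label noise, and the seed that fixes every random choice."""

    counts_per_class: tuple[int, int, int, int]
    language: str = "zh"
    label_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.counts_per_class) != 4 or any(c < 0 for c in self.counts_per_class):
            raise ValueError("counts_per_class must be 4 non-negative integers")
        if self.language not in LANGUAGES:
            raise ValueError(f"unknown language {self.language!r}; expected one of {LANGUAGES}")
        if not 0.0 <= self.label_noise_rate <= 1.0:
            raise ValueError("label_noise_rate must be in [0, 1]")


@dataclass(frozen=True)
class EmbeddingSimSpec:
    """Recipe for a simulated embedding dataset: a 4-class mixture on the
    unit sphere.  ``class_separation`` moves the class mean directions
    apart (0 = identical means, i.e. chance-level problem); larger values
    make the Bayes-optimal accuracy higher."""

    n_per_class: tuple[int, int, int, int]
    dim: int = 768
    within_class_spread: float = 0.1
    class_separation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_class) != 4 or any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be 4 non-negative integers")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.within_class_spread <= 0:
            raise ValueError("within_class_spread must be > 0")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")


# ---------------------------------------------------------------------------
# Template banks
#
# Each class has >= 20 templates per language; TEMPLATES[lang][cls][i] and
# PARAPHRASES[lang][cls][i] are light rewordings of each other (used for
# duplicate-pair generation).  Slots: {cond} condition, {intv} intervention,
# {outc} outcome measure, {pop} study population.
# ---------------------------------------------------------------------------

_EN_OBJECTIVE = [
    "This study aimed to investigate the effect of {intv} on {outc} in {pop} with {cond}.",
    "The purpose of this study was to evaluate whether {intv} improves {outc} among {pop} with {cond}.",
    "We aimed to explore the influence of {intv} on {outc} in {pop} suffering from {cond}.",
    "The objective of this work was to assess the efficacy of {intv} for {cond} in {pop}.",
    "This trial was designed to determine whether {intv} changes {outc} in {pop} with {cond}.",
    "We sought to examine the association between {intv} and {outc} in {pop} with {cond}.",
    "The goal of the present study was to clarify the role of {intv} in managing {cond} among {pop}.",
    "This study intended to compare the effect of {intv} and routine care on {outc} in {cond}.",
    "Our aim was to investigate whether {intv} benefits {outc} in {pop} diagnosed with {cond}.",
    "The present study was undertaken to evaluate the impact of {intv} on {outc} in {cond}.",
    "We aimed to assess the therapeutic value of {intv} for {pop} with {cond}.",
    "This investigation aimed to quantify the effect of {intv} on {outc} among {pop}.",
    "The study objective was to test the hypothesis that {intv} modulates {outc} in {cond}.",
    "We designed this study to explore how {intv} affects {outc} in {pop} with {cond}.",
    "The aim of this research was to observe the clinical efficacy of {intv} in treating {cond}.",
    "This study set out to evaluate changes in {outc} after {intv} in {pop} with {cond}.",
    "Our purpose was to determine the effectiveness and safety of {intv} for {cond} in {pop}.",
    "We aimed to identify whether {intv} can regulate {outc} in {pop} affected by {cond}.",
    "The primary objective was to examine the effect of {intv} on {outc} in patients with {cond}.",
    "This work aimed to provide evidence on the use of {intv} for improving {outc} in {cond}.",
]

_EN_OBJECTIVE_PARA = [
    "The aim of this study was to examine how {intv} affects {outc} in {pop} with {cond}.",
    "This study was conducted to assess whether {intv} can improve {outc} in {pop} with {cond}.",
    "Our goal was to investigate the impact of {intv} on {outc} among {pop} who have {cond}.",
    "This work set out to evaluate how effective {intv} is for {cond} in {pop}.",
    "The trial was planned to establish whether {intv} alters {outc} in {pop} with {cond}.",
    "We intended to study the relationship between {intv} and {outc} in {pop} with {cond}.",
    "The present study sought to define the role of {intv} in the management of {cond} in {pop}.",
    "The intention of this study was to compare {intv} with routine care regarding {outc} in {cond}.",
    "We wished to determine whether {intv} is beneficial for {outc} in {pop} diagnosed with {cond}.",
    "This study was carried out to examine the impact of {intv} on {outc} in {cond}.",
    "Our objective was to evaluate the therapeutic benefit of {intv} for {pop} with {cond}.",
    "The purpose of this investigation was to measure the effect of {intv} on {outc} in {pop}.",
    "We tested the hypothesis that {intv} influences {outc} in {cond}.",
    "The study was designed to clarify the effect of {intv} on {outc} in {pop} with {cond}.",
    "This research aimed to document the clinical efficacy of {intv} in the treatment of {cond}.",
    "The study aimed to track changes in {outc} following {intv} in {pop} with {cond}.",
    "We set out to establish the effectiveness and safety of {intv} for {cond} in {pop}.",
    "The aim was to find out whether {intv} regulates {outc} in {pop} affected by {cond}.",
    "The main objective was to study the influence of {intv} on {outc} in patients with {cond}.",
    "This study aimed to supply evidence for using {intv} to improve {outc} in {cond}.",
]

_EN_METHODS = [
    "A total of 120 {pop} with {cond} were randomly assigned to receive {intv} or usual care.",
    "{pop} with {cond} were enrolled and randomized into a treatment group receiving {intv} and a control group.",
    "Participants were recruited from outpatient clinics and allocated to {intv} or placebo using a random number table.",
    "{outc} was measured at baseline and after 8 weeks of {intv} in all enrolled {pop}.",
    "Eligible {pop} with {cond} received {intv} for 12 weeks, and {outc} was recorded before and after treatment.",
    "We conducted a randomized controlled trial comparing {intv} with conventional therapy in {pop} with {cond}.",
    "Patients were divided into two groups; the observation group was treated with {intv} while controls received standard care.",
    "{outc} and adverse events were assessed by blinded investigators throughout the {intv} protocol.",
    "A prospective cohort of {pop} with {cond} was followed for 6 months after starting {intv}.",
    "Blood samples were collected from all {pop} to determine {outc} before and after {intv}.",
    "The intervention group underwent {intv} three times per week, and {outc} was evaluated monthly.",
    "Baseline characteristics, {outc}, and treatment compliance were recorded for all participants with {cond}.",
    "We retrospectively analyzed the records of {pop} with {cond} who had been treated with {intv}.",
    "Randomization was stratified by disease severity, and both groups were followed with repeated measurement of {outc}.",
    "All enrolled {pop} completed questionnaires, and {outc} was quantified using standardized instruments after {intv}.",
    "The study protocol assigned {pop} with {cond} to {intv} combined with standard therapy or standard therapy alone.",
    "{outc} was determined by two independent assessors blinded to the {intv} allocation.",
    "Statistical analysis compared {outc} between the {intv} group and the control group using appropriate tests.",
    "A double-blind design was adopted, with {pop} receiving either {intv} or a matched placebo for the study of {cond}.",
    "Follow-up visits at 4, 8, and 12 weeks recorded {outc} and safety outcomes in {pop} undergoing {intv}.",
]

_EN_METHODS_PARA = [
    "One hundred and twenty {pop} with {cond} were randomized to {intv} or usual care.",
    "{pop} who had {cond} were recruited and randomly split into an {intv} arm and a control arm.",
    "Subjects recruited at outpatient clinics were randomly allocated to {intv} or placebo.",
    "In all enrolled {pop}, {outc} was assessed at baseline and again after 8 weeks of {intv}.",
    "{pop} with {cond} who met the criteria were given {intv} for 12 weeks, with {outc} measured pre- and post-treatment.",
    "A randomized controlled trial was performed to compare {intv} against conventional therapy in {pop} with {cond}.",
    "Two groups were formed; {intv} was given to the observation group and standard care to the controls.",
    "Blinded investigators evaluated {outc} and adverse events during the {intv} course.",
    "{pop} with {cond} entered a prospective cohort and were followed for six months after {intv} began.",
    "Before and after {intv}, blood was drawn from every participant to measure {outc}.",
    "{intv} was administered three times weekly in the intervention group, with monthly evaluation of {outc}.",
    "For every participant with {cond}, baseline data, {outc}, and compliance were documented.",
    "Records of {pop} with {cond} previously treated with {intv} were reviewed retrospectively.",
    "Allocation was stratified by severity, and {outc} was measured repeatedly in both groups.",
    "Questionnaires were completed by all {pop}, and standardized instruments quantified {outc} after {intv}.",
    "Per protocol, {pop} with {cond} received either {intv} plus standard therapy or standard therapy only.",
    "Two independent assessors, blinded to {intv} assignment, determined {outc}.",
    "{outc} in the {intv} and control groups was compared with suitable statistical tests.",
    "Using a double-blind design, {pop} were given {intv} or matched placebo in this study of {cond}.",
    "{outc} and safety endpoints were captured at 4-, 8-, and 12-week visits in {pop} receiving {intv}.",
]

_EN_RESULTS = [
    "After treatment, {outc} improved significantly in the {intv} group compared with controls (P<.05).",
    "{outc} decreased markedly following {intv}, while no significant change was observed in the control group.",
    "The {intv} group showed a significantly higher response rate than the control group among {pop} with {cond}.",
    "Compared with baseline, {outc} increased significantly after 12 weeks of {intv} (P<.01).",
    "Significant between-group differences in {outc} emerged at week 8 in favor of {intv}.",
    "{intv} was associated with a greater reduction in {outc} than standard care in {pop} with {cond}.",
    "The total effective rate reached 91.7% in the {intv} group versus 73.3% in controls (P<.05).",
    "No serious adverse events were observed, and {outc} remained stable in {pop} receiving {intv}.",
    "Post-treatment {outc} differed significantly between groups, with the larger improvement under {intv}.",
    "{outc} correlated with symptom relief after {intv} in {pop} with {cond} (P<.05).",
    "At follow-up, the improvement in {outc} persisted in the {intv} group but not in controls.",
    "The mean change in {outc} was significantly larger after {intv} than after placebo (P<.01).",
    "Subgroup analysis showed that {pop} with severe {cond} benefited most from {intv} in terms of {outc}.",
    "Levels of {outc} fell significantly in both groups, with a greater decline under {intv}.",
    "The incidence of complications was lower in the {intv} group than in the control group (P<.05).",
    "Treatment with {intv} significantly shortened recovery time and improved {outc} in {pop}.",
    "After 8 weeks, {outc} in the {intv} group was superior to that in the control group among {pop} with {cond}.",
    "Both groups improved over time, but the improvement in {outc} was significantly greater with {intv}.",
    "{outc} showed a statistically significant difference between the {intv} and control groups at endpoint.",
    "Adverse reactions were mild in the {intv} group, and {outc} improved in 85.0% of {pop} with {cond}.",
]

_EN_RESULTS_PARA = [
    "{outc} was significantly better in the {intv} group than in controls after treatment (P<.05).",
    "Following {intv}, {outc} fell markedly, whereas the control group showed no significant change.",
    "Among {pop} with {cond}, the response rate was significantly higher with {intv} than in controls.",
    "{outc} rose significantly from baseline after 12 weeks of {intv} (P<.01).",
    "By week 8, {outc} differed significantly between groups, favoring {intv}.",
    "In {pop} with {cond}, {intv} produced a larger drop in {outc} than standard care.",
    "The overall effective rate was 91.7% with {intv} against 73.3% in the control group (P<.05).",
    "{outc} stayed stable and no serious adverse events occurred in {pop} given {intv}.",
    "Between-group comparison after treatment showed significantly greater improvement in {outc} under {intv}.",
    "After {intv}, {outc} was correlated with symptom relief in {pop} with {cond} (P<.05).",
    "The gain in {outc} was maintained at follow-up in the {intv} group but not among controls.",
    "Mean {outc} changed significantly more after {intv} than after placebo (P<.01).",
    "In subgroups, {outc} improved most with {intv} among {pop} whose {cond} was severe.",
    "{outc} declined significantly in both arms, and the decline was larger with {intv}.",
    "Complications occurred less often in the {intv} group than among controls (P<.05).",
    "{intv} significantly reduced recovery time and bettered {outc} in {pop}.",
    "Among {pop} with {cond}, week-8 {outc} was better in the {intv} group than in the control group.",
    "Improvement occurred in both groups, yet the change in {outc} was significantly larger under {intv}.",
    "At the endpoint, {outc} differed significantly between the {intv} and control arms.",
    "In the {intv} group adverse reactions were mild and {outc} improved in 85.0% of {pop} with {cond}.",
]

_EN_CONCLUSION = [
    "These findings suggest that {intv} can effectively improve {outc} in {pop} with {cond}.",
    "In conclusion, {intv} appears to be a safe and effective option for managing {cond} in {pop}.",
    "Our results indicate that {intv} may benefit {outc} and deserves wider clinical application in {cond}.",
    "{intv} significantly improves {outc} in {pop} with {cond} and merits further large-scale study.",
    "The evidence supports the use of {intv} as an adjunct therapy for {cond}.",
    "Taken together, these data suggest that {intv} exerts a favorable effect on {outc} in {cond}.",
    "{intv} is worthy of clinical promotion for {pop} with {cond}, given its effect on {outc}.",
    "This study demonstrates that {intv} can regulate {outc} and alleviate symptoms of {cond}.",
    "We conclude that {intv} offers clinical value for improving {outc} in {pop} with {cond}.",
    "These results imply that {intv} may serve as a promising strategy for {cond} treatment.",
    "In summary, {intv} improved {outc} with good tolerability in {pop} with {cond}.",
    "The findings provide preliminary evidence that {intv} enhances {outc} in {cond}.",
    "{intv} combined with standard therapy may yield better control of {outc} in {pop} with {cond}.",
    "Clinicians may consider {intv} to improve {outc} in {pop} affected by {cond}.",
    "Overall, {intv} shows therapeutic potential for {cond}, particularly with respect to {outc}.",
    "These observations suggest a beneficial role of {intv} in the long-term management of {cond}.",
    "Our study supports {intv} as an effective measure to improve {outc} among {pop}.",
    "The results confirm that {intv} is effective and safe for treating {cond} in {pop}.",
    "{intv} may improve prognosis in {cond} by modulating {outc}, warranting confirmation in larger trials.",
    "In brief, {intv} represents a feasible approach to improving {outc} in {pop} with {cond}.",
]

_EN_CONCLUSION_PARA = [
    "The findings indicate that {intv} can effectively better {outc} in {pop} with {cond}.",
    "To conclude, {intv} seems a safe and effective way to manage {cond} in {pop}.",
    "The results suggest {intv} may improve {outc} and warrants broader clinical use in {cond}.",
    "In {pop} with {cond}, {intv} markedly improves {outc} and deserves larger studies.",
    "These data support using {intv} as adjunct therapy in {cond}.",
    "Collectively, the data indicate a favorable effect of {intv} on {outc} in {cond}.",
    "Given its effect on {outc}, {intv} merits clinical promotion for {pop} with {cond}.",
    "This work shows that {intv} can modulate {outc} and relieve symptoms of {cond}.",
    "It is concluded that {intv} has clinical value for improving {outc} in {pop} with {cond}.",
    "The results hint that {intv} could be a promising treatment strategy for {cond}.",
    "In short, {intv} improved {outc} and was well tolerated in {pop} with {cond}.",
    "These findings give preliminary evidence that {intv} raises {outc} in {cond}.",
    "Adding {intv} to standard therapy may achieve better control of {outc} in {pop} with {cond}.",
    "{intv} can be considered by clinicians to improve {outc} in {pop} with {cond}.",
    "On the whole, {intv} shows promise for {cond}, especially regarding {outc}.",
    "The observations point to a benefit of {intv} in long-term management of {cond}.",
    "This study backs {intv} as an effective way to improve {outc} in {pop}.",
    "The findings verify that {intv} is safe and effective for {cond} in {pop}.",
    "By modulating {outc}, {intv} may improve the prognosis of {cond}; larger trials should confirm this.",
    "Briefly, {intv} is a feasible means of improving {outc} in {pop} with {cond}.",
]

_ZH_OBJECTIVE = [
    "本研究旨在探讨{intv}对{cond}{pop}{outc}的影响。",
    "目的:评价{intv}对{cond}患者{outc}的改善作用。",
    "本文旨在观察{intv}治疗{cond}的临床疗效。",
    "研究目的为探索{intv}在{pop}{cond}治疗中的作用。",
    "本试验旨在明确{intv}能否改善{cond}患者的{outc}。",
    "本研究的目的是分析{intv}与{pop}{outc}之间的关系。",
    "旨在评估{intv}对{cond}{pop}的治疗价值。",
    "本研究拟比较{intv}与常规治疗对{cond}患者{outc}的影响。",
    "目的在于探讨{intv}改善{cond}患者{outc}的可行性。",
    "本研究旨在考察{intv}对{pop}{cond}预后的影响。",
    "为明确{intv}的疗效,本研究对{cond}{pop}进行了观察。",
    "研究旨在量化{intv}对{pop}{outc}的作用。",
    "本研究旨在验证{intv}调节{cond}患者{outc}的假设。",
    "目的:探讨{intv}对{cond}{pop}{outc}的调节作用及其意义。",
    "本研究旨在观察{intv}干预后{cond}患者{outc}的变化。",
    "旨在确定{intv}治疗{pop}{cond}的有效性与安全性。",
    "本研究目的为考察{intv}能否调控{cond}患者的{outc}。",
    "主要目的是研究{intv}对{cond}患者{outc}的影响。",
    "本文旨在为{intv}改善{cond}患者{outc}提供依据。",
    "研究目的:系统评价{intv}对{pop}{cond}的干预效果。",
]

_ZH_OBJECTIVE_PARA = [
    "本研究的目的是考察{intv}对{cond}{pop}{outc}的作用。",
    "目的在于评估{intv}能否改善{cond}患者的{outc}。",
    "本文目的为观察{intv}治疗{cond}的效果。",
    "本研究旨在探索{intv}在{pop}{cond}治疗中的价值。",
    "本试验目的是确定{intv}是否能够改善{cond}患者{outc}。",
    "本研究旨在分析{intv}与{pop}{outc}的相关性。",
    "目的是评价{intv}对{cond}{pop}的疗效。",
    "本研究比较了{intv}与常规治疗对{cond}患者{outc}的作用。",
    "本研究旨在探讨以{intv}改善{cond}患者{outc}的可能性。",
    "目的:考察{intv}对{pop}{cond}预后的作用。",
    "本研究观察{cond}{pop},以明确{intv}的疗效。",
    "本研究旨在测定{intv}对{pop}{outc}的影响大小。",
    "本研究检验了{intv}可调节{cond}患者{outc}这一假设。",
    "本文探讨{intv}对{cond}{pop}{outc}的调节及其临床意义。",
    "目的:观察{intv}干预后{cond}患者{outc}的改变。",
    "本研究旨在明确{intv}治疗{pop}{cond}的疗效和安全性。",
    "目的为研究{intv}对{cond}患者{outc}的调控作用。",
    "本研究主要考察{intv}对{cond}患者{outc}的作用。",
    "本研究旨在为{intv}改善{cond}患者{outc}提供证据。",
    "目的:系统观察{intv}对{pop}{cond}的干预作用。",
]

_ZH_METHODS = [
    "选取{cond}{pop}120例,随机分为{intv}组和对照组。",
    "将{pop}{cond}患者随机分为观察组与对照组,观察组给予{intv}。",
    "采用随机数字表法将入组患者分为{intv}组与安慰剂组。",
    "于基线及{intv}治疗8周后测定所有{pop}的{outc}。",
    "符合标准的{cond}{pop}接受{intv}治疗12周,治疗前后记录{outc}。",
    "开展随机对照试验,比较{intv}与常规治疗对{cond}{pop}的疗效。",
    "将患者分为两组,观察组采用{intv}治疗,对照组给予常规处理。",
    "由盲法评估者在{intv}疗程中记录{outc}及不良事件。",
    "对接受{intv}的{cond}{pop}进行为期6个月的前瞻性随访。",
    "采集所有{pop}的血样,于{intv}前后检测{outc}。",
    "干预组每周接受3次{intv},每月评估一次{outc}。",
    "记录所有{cond}患者的基线资料、{outc}及依从性。",
    "回顾性分析接受{intv}治疗的{cond}{pop}的临床资料。",
    "按病情严重程度分层随机,两组均多次复测{outc}。",
    "全部{pop}填写量表,{intv}后以标准化工具量化{outc}。",
    "方案规定{cond}{pop}接受{intv}联合常规治疗或单纯常规治疗。",
    "{outc}由两名对{intv}分组不知情的评估者独立测定。",
    "采用统计学方法比较{intv}组与对照组的{outc}差异。",
    "采用双盲设计,{pop}分别接受{intv}或安慰剂以研究{cond}。",
    "于第4、8、12周随访,记录接受{intv}的{pop}的{outc}与安全性指标。",
]

_ZH_METHODS_PARA = [
    "共纳入{cond}{pop}120例,随机分入{intv}组与对照组。",
    "{pop}{cond}患者被随机分为两组,观察组接受{intv}治疗。",
    "按随机数字表将入组者分配至{intv}组或安慰剂组。",
    "所有{pop}于基线和{intv}8周后检测{outc}。",
    "入选的{cond}{pop}行{intv}治疗12周,于治疗前后测定{outc}。",
    "进行随机对照研究,对比{intv}与常规治疗在{cond}{pop}中的效果。",
    "患者分为两组:观察组行{intv},对照组行常规处理。",
    "{intv}治疗期间由盲法评估者评定{outc}和不良事件。",
    "对行{intv}的{cond}{pop}随访6个月,采用前瞻性设计。",
    "于{intv}前后抽取所有{pop}血样检测{outc}。",
    "干预组{intv}每周3次,{outc}每月评估。",
    "对每位{cond}患者记录基线特征、{outc}与治疗依从性。",
    "对曾行{intv}治疗的{cond}{pop}病历进行回顾性分析。",
    "随机分组按严重程度分层,两组{outc}均重复测量。",
    "{pop}均完成问卷,{intv}后用标准化工具测量{outc}。",
    "按方案,{cond}{pop}接受{intv}加常规治疗或仅常规治疗。",
    "两名不知{intv}分组的评估者分别测定{outc}。",
    "比较{intv}组与对照组{outc},采用相应统计学检验。",
    "研究{cond}采用双盲设计,{pop}接受{intv}或对应安慰剂。",
    "在第4、8、12周访视时记录{intv}组{pop}的{outc}及安全性。",
]

_ZH_RESULTS = [
    "治疗后{intv}组{outc}较对照组明显改善,差异有统计学意义(P<0.05)。",
    "{intv}后{outc}显著下降,对照组无明显变化。",
    "{cond}{pop}中,{intv}组有效率显著高于对照组。",
    "与基线相比,{intv}治疗12周后{outc}显著升高(P<0.01)。",
    "第8周时两组{outc}差异显著,{intv}组优于对照组。",
    "{intv}组{outc}下降幅度大于常规治疗组。",
    "{intv}组总有效率为91.7%,对照组为73.3%,差异有统计学意义(P<0.05)。",
    "接受{intv}的{pop}未见严重不良事件,{outc}保持稳定。",
    "治疗后两组{outc}比较差异显著,{intv}组改善更明显。",
    "{intv}后{outc}与症状缓解程度相关(P<0.05)。",
    "随访时{intv}组{outc}的改善持续存在,对照组未见维持。",
    "{intv}组{outc}平均变化量显著大于安慰剂组(P<0.01)。",
    "亚组分析显示,重度{cond}{pop}经{intv}后{outc}获益最大。",
    "两组{outc}均显著下降,{intv}组下降更为明显。",
    "{intv}组并发症发生率低于对照组(P<0.05)。",
    "{intv}显著缩短恢复时间并改善{pop}的{outc}。",
    "8周后{cond}{pop}中{intv}组{outc}优于对照组。",
    "两组均有改善,但{intv}组{outc}改善幅度显著更大。",
    "终点时{intv}组与对照组{outc}差异有统计学意义。",
    "{intv}组不良反应轻微,85.0%的{cond}{pop}{outc}得到改善。",
]

_ZH_RESULTS_PARA = [
    "治疗后{intv}组{outc}改善优于对照组(P<0.05)。",
    "行{intv}后{outc}明显降低,而对照组变化不显著。",
    "在{cond}{pop}中,{intv}组的有效率明显高于对照组。",
    "{intv}12周后{outc}较基线显著上升(P<0.01)。",
    "治疗第8周两组{outc}出现显著差异,{intv}组更优。",
    "较常规治疗,{intv}使{outc}下降更多。",
    "总有效率{intv}组91.7%、对照组73.3%,差异显著(P<0.05)。",
    "{pop}行{intv}期间无严重不良事件,{outc}稳定。",
    "两组治疗后{outc}差异明显,以{intv}组改善为著。",
    "{intv}后{outc}与症状缓解相关(P<0.05)。",
    "随访显示{intv}组{outc}改善得以维持,对照组则否。",
    "{outc}平均变化量{intv}组显著高于安慰剂组(P<0.01)。",
    "亚组结果提示重度{cond}{pop}从{intv}中获益最明显。",
    "{outc}在两组均下降,{intv}组降幅更大。",
    "并发症发生率{intv}组低于对照组(P<0.05)。",
    "{intv}明显缩短了恢复时间,并使{pop}{outc}好转。",
    "治疗8周后,{intv}组{cond}{pop}的{outc}优于对照组。",
    "虽两组均改善,{intv}组{outc}的改善显著更大。",
    "研究终点两组{outc}比较差异有统计学意义。",
    "{intv}组不良反应轻,{cond}{pop}中85.0%{outc}改善。",
]

_ZH_CONCLUSION = [
    "结果提示{intv}可有效改善{cond}{pop}的{outc}。",
    "结论:{intv}治疗{pop}{cond}安全有效。",
    "本研究表明{intv}有助于改善{outc},值得在{cond}治疗中推广应用。",
    "{intv}能显著改善{cond}{pop}的{outc},值得进一步大样本研究。",
    "研究结果支持将{intv}作为{cond}的辅助治疗手段。",
    "综上,{intv}对{cond}患者{outc}具有良好的改善作用。",
    "鉴于其对{outc}的作用,{intv}值得在{cond}{pop}中临床推广。",
    "本研究证实{intv}可调节{outc}并缓解{cond}症状。",
    "我们认为{intv}对改善{cond}{pop}{outc}具有临床价值。",
    "上述结果提示{intv}可能成为{cond}治疗的有前景策略。",
    "总之,{intv}可改善{cond}{pop}的{outc},且耐受性良好。",
    "研究为{intv}提高{cond}患者{outc}提供了初步证据。",
    "{intv}联合常规治疗可更好地控制{cond}{pop}的{outc}。",
    "临床上可考虑应用{intv}改善{cond}{pop}的{outc}。",
    "总体而言,{intv}对{cond}具有治疗潜力,尤其体现在{outc}方面。",
    "以上结果提示{intv}在{cond}长期管理中具有益处。",
    "本研究支持{intv}作为改善{pop}{outc}的有效措施。",
    "结果证实{intv}治疗{pop}{cond}有效且安全。",
    "{intv}可能通过调节{outc}改善{cond}预后,有待大样本试验证实。",
    "简言之,{intv}是改善{cond}{pop}{outc}的可行方法。",
]

_ZH_CONCLUSION_PARA = [
    "提示{intv}能够有效改善{cond}{pop}的{outc}。",
    "结论为{intv}治疗{pop}{cond}是安全且有效的。",
    "结果表明{intv}可改善{outc},在{cond}治疗中值得推广。",
    "{intv}可明显改善{cond}{pop}{outc},宜行更大样本研究。",
    "结果支持{intv}用作{cond}的辅助治疗。",
    "综合来看,{intv}能较好地改善{cond}患者的{outc}。",
    "考虑其改善{outc}的作用,{intv}适合在{cond}{pop}中推广。",
    "研究证实{intv}能调控{outc},减轻{cond}症状。",
    "认为{intv}在改善{cond}{pop}{outc}方面具有应用价值。",
    "结果提示{intv}或可成为治疗{cond}的一种有前景的方法。",
    "总而言之,{intv}改善了{cond}{pop}的{outc},耐受性好。",
    "本研究为{intv}改善{cond}患者{outc}提供了初步依据。",
    "{intv}与常规治疗联合可更有效控制{cond}{pop}{outc}。",
    "临床可考虑以{intv}改善{cond}{pop}{outc}。",
    "整体上{intv}对{cond}有治疗潜力,在{outc}方面尤为明显。",
    "结果提示{intv}有益于{cond}的长期管理。",
    "研究支持{intv}是改善{pop}{outc}的有效手段。",
    "结果证明{intv}对{pop}{cond}的治疗有效且安全。",
    "{intv}或通过调节{outc}改善{cond}预后,尚需大样本试验验证。",
    "简而言之,{intv}是改善{cond}{pop}{outc}的可行手段。",
]

TEMPLATES: dict[str, dict[str, list[str]]] = {
    "en": {
        "objective": _EN_OBJECTIVE,
        "methods": _EN_METHODS,
        "results": _EN_RESULTS,
        "conclusion": _EN_CONCLUSION,
    },
    "zh": {
        "objective": _ZH_OBJECTIVE,
        "methods": _ZH_METHODS,
        "results": _ZH_RESULTS,
        "conclusion": _ZH_CONCLUSION,
    },
}

PARAPHRASES: dict[str, dict[str, list[str]]] = {
    "en": {
        "objective": _EN_OBJECTIVE_PARA,
        "methods": _EN_METHODS_PARA,
        "results": _EN_RESULTS_PARA,
        "conclusion": _EN_CONCLUSION_PARA,
    },
    "zh": {
        "objective": _ZH_OBJECTIVE_PARA,
        "methods": _ZH_METHODS_PARA,
        "results": _ZH_RESULTS_PARA,
        "conclusion": _ZH_CONCLUSION_PARA,
    },
}

_TOPICS = {
    "en": {
        "cond": [
            "type 2 diabetes", "chronic heart failure", "essential hypertension",
            "rheumatoid arthritis", "chronic hepatitis B", "ischemic stroke",
            "major depressive disorder", "bronchial asthma", "chronic kidney disease",
            "gastric cancer", "osteoporosis", "atrial fibrillation",
            "knee osteoarthritis", "chronic gastritis", "coronary heart disease",
            "lumbar disc herniation", "chronic obstructive pulmonary disease",
            "functional dyspepsia", "irritable bowel syndrome", "insomnia disorder",
            "diabetic peripheral neuropathy", "cervical spondylosis",
            "ulcerative colitis", "polycystic ovary syndrome",
        ],
        "intv": [
            "acupuncture therapy", "a modified Buyang Huanwu decoction",
            "low-dose aspirin", "cognitive behavioral therapy",
            "metformin combined therapy", "tai chi exercise", "electroacupuncture",
            "a Chinese herbal compound", "statin therapy", "moxibustion",
            "warm needling", "aerobic exercise training", "auricular point pressing",
            "Liuwei Dihuang pills", "massage therapy", "mindfulness training",
            "a probiotic preparation", "vitamin D supplementation",
            "Danshen injection", "respiratory rehabilitation training",
        ],
        "outc": [
            "fasting blood glucose", "left ventricular ejection fraction",
            "serum creatinine levels", "pain scores", "quality of life scores",
            "inflammatory cytokine levels", "24-hour ambulatory blood pressure",
            "bone mineral density", "glycated hemoglobin", "sleep quality scores",
            "serum lipid profiles", "depression scale scores",
            "six-minute walking distance", "gastric emptying rate",
            "joint function scores", "oxidative stress markers",
        ],
        "pop": [
            "elderly inpatients", "community-dwelling adults",
            "postoperative patients", "outpatients", "middle-aged women",
            "patients aged 45 to 75 years", "elderly male patients",
            "perimenopausal women", "newly diagnosed patients",
            "rural community residents", "obese adults", "long-term care residents",
        ],
    },
    "zh": {
        "cond": [
            "2型糖尿病", "慢性心力衰竭", "原发性高血压", "类风湿关节炎",
            "慢性乙型肝炎", "缺血性脑卒中", "抑郁症", "支气管哮喘",
            "慢性肾脏病", "胃癌", "骨质疏松症", "心房颤动",
            "膝骨关节炎", "慢性胃炎", "冠心病", "腰椎间盘突出症",
            "慢性阻塞性肺疾病", "功能性消化不良", "肠易激综合征", "失眠症",
            "糖尿病周围神经病变", "颈椎病", "溃疡性结肠炎", "多囊卵巢综合征",
        ],
        "intv": [
            "针刺治疗", "补阳还五汤加减", "小剂量阿司匹林", "认知行为疗法",
            "二甲双胍联合治疗", "太极拳锻炼", "电针", "中药复方",
            "他汀类药物", "艾灸", "温针灸", "有氧运动训练",
            "耳穴压豆", "六味地黄丸", "推拿治疗", "正念训练",
            "益生菌制剂", "维生素D补充", "丹参注射液", "呼吸康复训练",
        ],
        "outc": [
            "空腹血糖", "左室射血分数", "血清肌酐水平", "疼痛评分",
            "生活质量评分", "炎症因子水平", "24小时动态血压", "骨密度",
            "糖化血红蛋白", "睡眠质量评分", "血脂水平", "抑郁量表评分",
            "6分钟步行距离", "胃排空率", "关节功能评分", "氧化应激指标",
        ],
        "pop": [
            "老年住院患者", "社区成年人", "术后患者", "门诊患者",
            "中年女性", "45至75岁患者", "老年男性患者", "围绝经期女性",
            "初诊患者", "农村社区居民", "肥胖成年人", "长期照护机构老年人",
        ],
    },
}


def _draw_topic(rng: np.random.Generator, language: str) -> dict[str, str]:
    bank = _TOPICS[language]
    return {slot: bank[slot][rng.integers(len(bank[slot]))] for slot in ("cond", "intv", "outc", "pop")}


def _render(template: str, topic: dict[str, str]) -> str:
    return template.format(**topic)


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_abstract_corpus(spec: CorpusSpec) -> list[SentenceRecord]:
    """Generate a labelled synthetic corpus of abstract sentences.

    Sentences are grouped into abstracts: each abstract draws one topic
    tuple and contains its sentences in objective -> methods -> results ->
    conclusion order.  Exactly ``spec.counts_per_class[c]`` sentences of
    class ``c`` are produced (before label noise); with
    ``label_noise_rate`` r > 0, ``floor(r * total)`` labels are
    reassigned uniformly to a wrong class.  Fully deterministic in
    ``spec``.
    """
    bank = TEMPLATES[spec.language]
    for cls in CLASSES:
        if len(bank[cls]) < 20:
            raise ValueError(f"template bank for {spec.language}/{cls} has fewer than 20 templates")
    counts = tuple(int(c) for c in spec.counts_per_class)
    total = sum(counts)
    if total == 0:
        raise ValueError("all class counts are zero; nothing to generate")

    rng = np.random.default_rng(spec.seed)
    # ~8 sentences per abstract (2 per section on average)
    n_abstracts = max(1, int(round(total / 8)))

    # Distribute each class's count across abstracts as evenly as possible;
    # a seeded permutation decides which abstracts take the remainder.
    per_abstract = np.zeros((n_abstracts, 4), dtype=int)
    for c, count in enumerate(counts):
        base, rem = divmod(count, n_abstracts)
        per_abstract[:, c] = base
        if rem:
            extra = rng.permutation(n_abstracts)[:rem]
            per_abstract[extra, c] += 1

    records: list[SentenceRecord] = []
    for a in range(n_abstracts):
        abstract_id = f"a{a:05d}"
        topic = _draw_topic(rng, spec.language)
        sentence_index = 0
        for c, cls in enumerate(CLASSES):
            templates = bank[cls]
            for _ in range(per_abstract[a, c]):
                t = templates[rng.integers(len(templates))]
                records.append(SentenceRecord(
                    text=_render(t, topic),
                    abstract_id=abstract_id,
                    sentence_index=sentence_index,
                    label=cls,
                ))
                sentence_index += 1

    if spec.label_noise_rate > 0:
        n_noisy = int(math.floor(spec.label_noise_rate * total))
        noisy_idx = rng.choice(total, size=n_noisy, replace=False)
        for i in noisy_idx:
            old = records[i].label
            wrong = [c for c in CLASSES if c != old]
            new = wrong[rng.integers(3)]
            r = records[i]
            records[i] = SentenceRecord(text=r.text, abstract_id=r.abstract_id,
                                        sentence_index=r.sentence_index, label=new)
    return records


def generate_duplicate_pairs(n_pairs: int, language: str = "zh",
                             seed: int = 0) -> list[tuple[str, str]]:
    """Generate sentence pairs expressing the same content.

    Each pair renders a template and its paired light paraphrase with the
    same topic slots; used to pretrain the autoencoder branch of the
    supervised classifier on duplicate embeddings.
    """
    if language not in LANGUAGES:
        raise ValueError(f"unknown language {language!r}")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        cls = CLASSES[rng.integers(4)]
        i = int(rng.integers(len(TEMPLATES[language][cls])))
        topic = _draw_topic(rng, language)
        pairs.append((_render(TEMPLATES[language][cls][i], topic),
                      _render(PARAPHRASES[language][cls][i], topic)))
    return pairs


# ---------------------------------------------------------------------------
# Embedding simulation
# ---------------------------------------------------------------------------

def simulate_embeddings(spec: EmbeddingSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Simulate unit-norm embeddings from a 4-class spherical mixture.

    The class mean directions are ``normalize(b + s * u_c)`` where ``b``
    and ``u_1..u_4`` are seeded orthonormal vectors and ``s`` is
    ``class_separation``: at s=0 all means coincide (chance-level
    problem), and the pairwise angular distance between means grows
    monotonically with s toward orthogonality.  Points are
    ``normalize(mu_c + spread * g)``, g standard normal.

    Returns ``(values, labels)`` with values of shape (n, dim), every
    row unit-norm, and integer labels in [0, 4).
    """
    rng = np.random.default_rng(spec.seed)
    dim, spread, sep = spec.dim, spec.within_class_spread, spec.class_separation
    n_total = sum(spec.n_per_class)
    if n_total == 0:
        return np.zeros((0, dim)), np.zeros(0, dtype=int)
    if dim < 5:
        # need 5 orthonormal directions (base + 4 class axes)
        raise ValueError("dim must be >= 5 for 4 separable classes")

    q, _ = np.linalg.qr(rng.normal(size=(dim, 5)))
    base, axes = q[:, 0], q[:, 1:]
    means = base[:, None] + sep * axes  # (dim, 4)
    means /= np.linalg.norm(means, axis=0, keepdims=True)

    values = np.empty((n_total, dim))
    labels = np.empty(n_total, dtype=int)
    row = 0
    for c, n in enumerate(spec.n_per_class):
        pts = means[:, c][None, :] + spread * rng.normal(size=(n, dim))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        values[row:row + n] = pts
        labels[row:row + n] = c
        row += n
    return values, labels


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_corpus(records: list[SentenceRecord], train_fraction: float,
                 test_fraction: float, seed: int = 0,
                 ) -> tuple[list[SentenceRecord], list[SentenceRecord]]:
    """Split a corpus into disjoint train/test lists, atomically by abstract.

    No abstract straddles the split, so near-duplicate sentences from one
    abstract cannot leak across it.  Both sides are guaranteed nonempty.
    """
    if train_fraction <= 0 or test_fraction <= 0:
        raise ValueError("fractions must be positive (both sides nonempty)")
    if abs(train_fraction + test_fraction - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    abstract_ids = sorted({r.abstract_id for r in records})
    if len(abstract_ids) < 2:
        raise ValueError("need at least 2 abstracts to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(abstract_ids))
    n_train = int(round(train_fraction * len(abstract_ids)))
    n_train = min(max(n_train, 1), len(abstract_ids) - 1)
    train_ids = {abstract_ids[i] for i in order[:n_train]}
    train = [r for r in records if r.abstract_id in train_ids]
    test = [r for r in records if r.abstract_id not in train_ids]
    return train, test
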