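# Default vendor-term harmonization map: raw (Q)SAR output terms from the
# three commercial vendors to the common four-category vocabulary
# (POSITIVE / NEGATIVE / EQUIVOCAL / OOD).
#
# The Lhasa rule-based system has no equivocal output category: alerting
# structures whose reasoning level is equivocal or higher count as POSITIVE,
# negatives with misclassified features count as NEGATIVE, and negatives
# with unclassified features are treated as out-of-domain.
normalize: true
vendors:
  Leadscope:
    statistical:
      preferred:
        POSITIVE: Positive
        NEGATIVE: Negative
        EQUIVOCAL: Indeterminate
        OOD: Not in domain
      terms:
        Positive: POSITIVE
        Negative: NEGATIVE
        Indeterminate: EQUIVOCAL
        Not in domain: OOD
    rule_based:
      preferred:
        POSITIVE: Positive
        NEGATIVE: Negative
        EQUIVOCAL: Indeterminate
        OOD: Not in domain
      terms:
        Positive: POSITIVE
        Negative: NEGATIVE
        Indeterminate: EQUIVOCAL
        Not in domain: OOD
  MultiCASE:
    statistical:
      preferred:
        POSITIVE: Positive
        NEGATIVE: Negative
        EQUIVOCAL: Inconclusive
        OOD: Out of domain
      terms:
        Positive: POSITIVE
        Negative: NEGATIVE
        Inconclusive: EQUIVOCAL
        Out of domain: OOD
    rule_based:
      preferred:
        POSITIVE: Positive
        NEGATIVE: Negative
        EQUIVOCAL: Inconclusive
        OOD: Out of domain
      terms:
        Positive: POSITIVE
        Negative: NEGATIVE
        Inconclusive: EQUIVOCAL
        Out of domain: OOD
  Lhasa:
    statistical:
      preferred:
        POSITIVE: Positive
        NEGATIVE: Negative
        EQUIVOCAL: Equivocal
        OOD: Outside domain
      terms:
        Positive: POSITIVE
        Negative: NEGATIVE
        Equivocal: EQUIVOCAL
        Outside domain: OOD
    rule_based:
      forbidden: [EQUIVOCAL]
      preferred:
        POSITIVE: Alerting structure (plausible)
        NEGATIVE: Negative
        OOD: Negative with unclassified features
      terms:
        Alerting structure with reasoning of equivocal or higher: POSITIVE
        Alerting structure (certain): POSITIVE
        Alerting structure (probable): POSITIVE
        Alerting structure (plausible): POSITIVE
        Alerting structure (equivocal): POSITIVE
        Negative: NEGATIVE
        Negative with misclassified features: NEGATIVE
        Negative with unclassified features: OOD
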