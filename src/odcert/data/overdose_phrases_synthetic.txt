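# Synthetic stand-in phrase list (37 entries) for the rule-based
# overdose classifier.  These are common overdose-indicative words and
# bigrams from public OD-surveillance vocabulary, assembled for this
# package; they are NOT a jurisdiction's operational list.  Replace with
# your own list via --phrases / RunConfig.phrase_path.
OVERDOSE
TOXICITY
INTOXICATION
POISONING
POLYSUBSTANCE
POLYPHARMACY
HEROIN
FENTANYL
CARFENTANIL
ACETYLFENTANYL
COCAINE
METHAMPHETAMINE
AMPHETAMINE
OXYCODONE
HYDROCODONE
OXYMORPHONE
HYDROMORPHONE
MORPHINE
CODEINE
METHADONE
BUPRENORPHINE
TRAMADOL
ALPRAZOLAM
DIAZEPAM
CLONAZEPAM
BENZODIAZEPINE
GABAPENTIN
ETHANOL
OPIATE
OPIOID
NARCOTIC
DRUG OVERDOSE
MIXED DRUG
DRUG TOXICITY
DRUG INTOXICATION
ACCIDENTAL OVERDOSE
ILLICIT DRUG
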