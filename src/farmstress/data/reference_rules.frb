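# farmstress rule base v1
# Nine-rule reference base for work-related stress & anxiety inference.
# Antecedents of rules 1-4 are transcribed from the published rule list;
# rules 5-9 are synthetic reconstructions (only their support/confidence
# values are published) chosen to cover the term space consistently with
# the published factor polarities.  Support/confidence annotations are the
# published per-rule values; lift/p were not published.
PCG=depressed & FIN=deteriorating & SCF=mild_association & TECH=negative_impact => WRS=high | support=0.36 confidence=0.76 lift=nan p=nan
PCG=labile & FIN=not_changed & SCF=moderate_association & TECH=positive_impact => WRS=moderate | support=0.39 confidence=0.92 lift=nan p=nan
PCG=normal_mental_health & FIN=not_changed & SCF=not_associated & TECH=positive_impact => WRS=very_low | support=0.45 confidence=0.71 lift=nan p=nan
PCG=depressed & FIN=deteriorating & SCF=strong_association & TECH=negative_impact => WRS=extremely_high | support=0.56 confidence=0.57 lift=nan p=nan
PCG=anxious & FIN=improved & SCF=strong_association & TECH=positive_impact => WRS=extremely_high | support=0.62 confidence=0.35 lift=nan p=nan
PCG=depressed & FIN=not_changed & SCF=moderate_association & TECH=no_impact => WRS=high | support=0.72 confidence=0.63 lift=nan p=nan
PCG=labile & FIN=deteriorating & SCF=mild_association & TECH=no_impact => WRS=moderate | support=0.41 confidence=0.53 lift=nan p=nan
PCG=labile & FIN=not_changed & SCF=mild_association & TECH=no_impact => WRS=low | support=0.52 confidence=0.56 lift=nan p=nan
PCG=normal_mental_health & FIN=improved & SCF=not_associated & TECH=no_impact => WRS=very_low | support=0.51 confidence=0.67 lift=nan p=nan
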