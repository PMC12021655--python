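As a diagnostician, read the clinical note below and propose the complete set of conditions that could account for the presentation, citing the findings behind each.
Answer with numbered diagnoses and dash-prefixed supporting findings.

[NOTE]
$note
[/NOTE]
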