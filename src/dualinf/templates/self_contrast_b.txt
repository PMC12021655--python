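Consider the patient described below. Which diseases belong on the differential, and which documented findings argue for each of them? Be thorough and do not omit plausible alternatives.
Answer with numbered diagnoses and dash-prefixed supporting findings.

[NOTE]
$note
[/NOTE]
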