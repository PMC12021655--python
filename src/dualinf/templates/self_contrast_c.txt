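Review the following clinical note as if preparing for a case conference: enumerate every condition worth ruling in or out, together with the evidence in the note that raises it.
Answer with numbered diagnoses and dash-prefixed supporting findings.

[NOTE]
$note
[/NOTE]
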