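Three independent drafts of a differential diagnosis for the clinical note below disagree about the diagnoses listed in the disputed block at the end. Re-examine the note, arbitrate each disputed diagnosis on the evidence, and produce the final differential.
Answer with numbered diagnoses and dash-prefixed supporting findings.

[NOTE]
$note
[/NOTE]
[DISPUTED]
$disputed
[/DISPUTED]
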