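Read the clinical note below and work out a differential diagnosis step by step: first identify the salient findings, then reason carefully about which conditions those findings point to.
Give your final answer as numbered diagnoses, each followed by dash-prefixed supporting findings from the note.

[NOTE]
$note
[/NOTE]
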