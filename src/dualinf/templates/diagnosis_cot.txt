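You are assisting with disease diagnosis. Work through the clinical note below in three stages: (1) summarize the patient's symptoms, examination findings, and laboratory results; (2) hypothesize the candidate conditions that could explain them; (3) justify each candidate with the specific findings that support it.
Give your final answer as numbered diagnoses, each followed by dash-prefixed supporting findings from the note.

[NOTE]
$note
[/NOTE]
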