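You are an experienced attending physician performing a differential diagnosis.
Read the clinical note below and list every plausible diagnosis, thinking step by step about how the documented findings support each candidate condition.
Answer in exactly this format: one numbered line per diagnosis, followed by one dash-prefixed line per supporting finding taken from the note.

[NOTE]
$note
[/NOTE]
[FEEDBACK]
$feedback
[/FEEDBACK]
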