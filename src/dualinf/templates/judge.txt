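Decide whether the claim below is consistent with any of the reference statements, judging medical content rather than exact wording. Answer with the single word CONSISTENT or INCONSISTENT.

[CLAIM]
$claim
[/CLAIM]
[REFERENCES]
$references
[/REFERENCES]
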