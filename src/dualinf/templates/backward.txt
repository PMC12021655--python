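For each candidate diagnosis listed below, recall all of the representative symptoms, physical-examination findings, and laboratory test results that the condition typically presents with.
Answer with one numbered line per diagnosis and one dash-prefixed line per recalled finding.

[DIAGNOSES]
$diagnoses
[/DIAGNOSES]
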