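# Section header patterns: pattern<TAB>section kind.
# Matched case-insensitively at the start of a line, optional trailing colon.
clinical details	clinical_details
clinical history	clinical_details
clinical information	clinical_details
history	clinical_details
indication	clinical_details
report	report_body
findings	report_body
scan findings	report_body
conclusion	conclusion
conclusions	conclusion
impression	conclusion
comment	conclusion
opinion	conclusion
summary	conclusion
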