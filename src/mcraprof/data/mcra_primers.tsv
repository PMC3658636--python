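name	forward	reverse	mid_tag	expected_amplicon_bp
ML	GGTGGTGTMGGATTCACACARTAYGCWACAGC	TTCATTGCRTAGTTWGGRTAGTT		470
MCR	TAYGAYCARATHTGGYT	ACRTTCATNGCRTARTT		500
ME	GCMATGCARATHGGWATGTC	TCATKGCRTAGTTDGGRTAGT		760
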