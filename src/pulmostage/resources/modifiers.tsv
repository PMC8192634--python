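category	direction	pattern
negation	forward	no evidence of
negation	forward	no
negation	forward	without
negation	forward	absence of
negation	forward	free of
negation	forward	not
negation	backward	absent
negation	backward	ruled out
uncertainty	forward	possible
uncertainty	forward	possibly
uncertainty	forward	probable
uncertainty	forward	probably
uncertainty	forward	likely
uncertainty	forward	suspicious for
uncertainty	forward	suspected
uncertainty	forward	may represent
uncertainty	forward	suggestive of
uncertainty	forward	cannot exclude
uncertainty	forward	questionable
uncertainty	forward	abutting
uncertainty	forward	abuts
uncertainty	forward	extending towards?
uncertainty	forward	in close relation to
historical	forward	prior
historical	forward	previous
historical	forward	previously
historical	forward	history of
historical	forward	status post
termination	bidirectional	but
termination	bidirectional	however
termination	bidirectional	although
termination	bidirectional	whereas
termination	bidirectional	;
pseudo	forward	no change
pseudo	forward	no interval change
pseudo	forward	no significant change
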