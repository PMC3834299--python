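strain	EhV-86	EhV-84	EhV-88	EhV-163	EhV-201	EhV-205	EhV-202	EhV-208	EhV-207
92	-	-	-	-	-	-	-	-	-
92A	-	-	-	-	-	-	-	-	-
92D	-	-	-	-	-	-	-	-	-
92E	-	-	-	-	-	-	-	-	-
92F	+	+	+	+	+	+	+	+	+
CCMP379	-	-	-	-	-	-	-	-	-
CCMP374	+	+	+	+	+	+	+	+	+
CCMP373	-	-	-	-	-	-	-	-	-
12-1	-	-	+	+	+	+	+	+	+
CCMP1516	+	+	+	-	+	+	+	+	+
Van 556	-	-	-	-	-	-	-	-	-
CH 24/90	-	-	-	-	-	-	-	+	-
CH 25/90	-	-	-	-	-	-	-	-	-
L	+	+	+	+	+	-	+	+	+
NZEH	-	-	-	-	-	-	-	-	-
EH2	+	+	+	-	+	+	+	+	+
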