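<ROSETTASCRIPTS>
	<MOVERS>
		<LoopFinder name = find ch1 = 0 ch2 = 1 interface = 1 min_length = 3 max_length = 10 mingap = 2/> Find loops on chain 2 with length between 3 and 10, with at least 3 residue separation.
		<LoopRemodel name = build auto_loops = 1 design = 0 protocol = kinematic perturb = 1 refine = 0/> Aggressively build found loops, no design
		<LoopRemodel name = refine1 auto_loops = 1 design = 0 protocol = kinematic perturb = 0 refine = 1 refine_score = soft_rep/> Refine found loops, soft repulsive, no design
		<LoopRemodel name = refine2 auto_loops = 1 design = 1 protocol = kinematic perturb = 0 refine = 1 refine_score = score12/> Refine found loops, score12, design
		<Backrub name = backrub partner1 = 0 partner2 = 1/> Subtle backbone moves over whole interface of chain 2
		<LoopOver name = repeat_backrub mover_name = backrub iterations = 10/> Bundles Backrub into repeats (no filter used)
		<RepackMinimize name = des1 scorefxn_repack = score_docking scorefxn_minimize = soft_rep minimize_bb = 0 minimize_rb = 0/> Aggressive design scorefunction, sidechain only moves
		<RepackMinimize name = des2 scorefxn_repack = soft_rep scorefxn_minimize = score12 minimize_bb = 0 minimize_rb = 1/> More constrained design scorefunction, sidechain and rigid body moves
		<RepackMinimize name = des3 design_partner1 = 1 design_partner2 = 1 minimize_bb = 1/> Strict design scorefunction, sidechain, rigid body, and backbone moves
		<ParsedProtocol name = design>
			<Add mover_name = des1/>
			<Add mover_name = des2/>
			<Add mover_name = des3/>
		</ParsedProtocol>
	</MOVERS>
	<PROTOCOLS>
		<Add mover = find/>
		<Add mover = build/>
		<Add mover = refine1/>
		<Add mover = refine2/>
		<Add mover = repeat_backrub/>
		<Add mover = design/>
	</PROTOCOLS>
</ROSETTASCRIPTS>
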