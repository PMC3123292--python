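<ROSETTASCRIPTS>
	<FILTERS>
		<Ddg name = ddG scorefxn = score12 threshold = -15 repeats = 2/> binding energy calculation; an average of two repeats is computed for better numerical accuracy
		<Sasa name = sasa threshold = 800/> Buried surface area upon complex formation
		<Rmsd name = rmsd confidence = 0/> confidence = 0 means that the filter will be evaluated but not used as an acceptance criterion
		<CompoundStatement name = ddg_sasa> combine filters into a single logical statement
			<AND filter_name = ddG/>
			<AND filter_name = sasa/>
		</CompoundStatement>
	</FILTERS>
	<MOVERS>
		<Docking name = docking score_high = soft_rep fullatom = 1 local_refine = 1/> Invokes local-refinement (in full-atom) with a soft potential
		<Backrub name = backrub partner1 = 0 partner2 = 1 interface_distance_cutoff = 8.0 moves = 1000 sc_move_probability = 0.25 scorefxn = score12
			small_move_probability = 0.15 bbg_move_probability = 0.25/> perturb the backbone of chain2
		<RepackMinimize name = des1 scorefxn_repack = soft_rep scorefxn_minimize = soft_rep minimize_bb = 0 minimize_rb = 1/>
		<RepackMinimize name = des2 scorefxn_repack = score12 scorefxn_minimize = score12 minimize_bb = 0 minimize_rb = 1/> Design and minimization at the interface
		<RepackMinimize name = des3 minimize_bb = 1/>
		<ParsedProtocol name = design>
			<Add mover_name = des1/>
			<Add mover_name = des2/>
			<Add mover_name = des3/>
			<Add mover_name = backrub/>
			<Add mover_name = des3 filter_name = ddg_sasa/>
		</ParsedProtocol>
		<GenericMonteCarlo name = iterate scorefxn_name = score12 mover_name = design trials = 10/>
	</MOVERS>
	<PROTOCOLS>
		<Add mover = docking/>
		<Add mover = iterate/>
		<Add filter = ddG/>
		<Add filter = sasa/>
		<Add filter = rmsd/>
	</PROTOCOLS>
</ROSETTASCRIPTS>
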